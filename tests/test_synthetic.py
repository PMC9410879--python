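import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribostop.readmodel import classify_sizes, parse_annotation
from ribostop.synthetic_data import (
    ConfigError,
    SimulationConfig,
    footprint_length,
    simulate_reads,
    simulate_transcriptome,
    write_transcriptome,
)


class TestConfig:
    def test_geometry_invariant_enforced(self):
        with pytest.raises(ConfigError, match="geometry"):
            SimulationConfig(full_footprint=30)

    def test_cds_must_fit_two_footprints(self):
        with pytest.raises(ConfigError, match="cds_length_range"):
            SimulationConfig(cds_length_range=(40, 60))

    def test_probabilities_bounded(self):
        with pytest.raises(ConfigError, match="cleavage_rate"):
            SimulationConfig(cleavage_rate=1.5)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError, match="model"):
            SimulationConfig(model="model3")

    def test_human_preset_shifts_geometry(self):
        cfg = SimulationConfig.human_preset()
        assert cfg.full_footprint == 31
        assert cfg.downstream_protect == 13
        assert cfg.intermediate_ladder == (1, 4, 7, 10)


class TestFootprintGeometry:
    cfg = SimulationConfig()

    @pytest.mark.parametrize("dist,length", [(10, 28), (7, 25), (4, 22), (1, 19), (0, 18)])
    def test_protection_lengths(self, dist, length):
        assert footprint_length(dist, self.cfg) == length

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            footprint_length(-1, self.cfg)

    @given(st.integers(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_clamped(self, d):
        L = footprint_length(d, self.cfg)
        assert L <= self.cfg.full_footprint
        if d > 0:
            assert L >= footprint_length(d - 1, self.cfg)

    def test_codon_ladder_steps_of_three(self):
        lengths = [footprint_length(d, self.cfg) for d in (1, 4, 7)]
        assert lengths == [19, 22, 25]
        assert all(b - a == 3 for a, b in zip(lengths, lengths[1:]))


class TestTranscriptome:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_genes=30, seed=7)
        a = simulate_transcriptome(cfg)
        b = simulate_transcriptome(cfg)
        assert [g.sequence for g in a.genes] == [g.sequence for g in b.genes]
        assert [g.weight for g in a.genes] == [g.weight for g in b.genes]

    def test_cds_lengths_in_range_and_codon_multiple(self):
        cfg = SimulationConfig(n_genes=50, cds_length_range=(300, 600), seed=1)
        for g in simulate_transcriptome(cfg).genes:
            assert 300 <= g.model.cds_length <= 600
            assert g.model.cds_length % 3 == 0
            assert g.sequence[g.model.stop_codon_pos:g.model.stop_codon_pos + 3] == "TAA"

    def test_uniform_expression_allocates_evenly(self):
        cfg = SimulationConfig(n_genes=50, depth=100_000, race_depth=100, seed=3)
        trome = simulate_transcriptome(cfg)
        sim = simulate_reads(trome, cfg)
        counts = sim.ribo["gene_id"].value_counts()
        p = 1 / 50
        sd = np.sqrt(100_000 * p * (1 - p))
        assert (np.abs(counts - 100_000 * p) <= 3 * sd).all()

    def test_gff_fasta_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=10, seed=4)
        trome = simulate_transcriptome(cfg)
        write_transcriptome(trome, tmp_path / "a.gff3", tmp_path / "s.fa")
        parsed = {t.gene_id: t for t in parse_annotation(tmp_path / "a.gff3")}
        for g in trome.genes:
            tm = parsed[g.model.gene_id]
            assert tm.stop_codon_pos == g.model.stop_codon_pos
            assert tm.spliced_length == g.model.spliced_length
            assert tm.n_annotated_stops == 1


class TestReadSimulation:
    def test_seeded_reads_identical(self):
        cfg = SimulationConfig(n_genes=20, depth=5000, race_depth=5000, seed=9)
        trome = simulate_transcriptome(cfg)
        a = simulate_reads(trome, cfg)
        b = simulate_reads(trome, cfg)
        pd.testing.assert_frame_equal(a.ribo, b.ribo)
        pd.testing.assert_frame_equal(a.race_plus_pnk, b.race_plus_pnk)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_model1_short_footprints_end_in_stop_codon(self):
        cfg = SimulationConfig(
            n_genes=20, depth=20_000, race_depth=100, seed=2,
            model="model1_Asite", cleavage_rate=1.0, ire1_rate=0.0,
            termination_rate=0.0,
        )
        trome = simulate_transcriptome(cfg)
        sim = simulate_reads(trome, cfg)
        stops = {g.model.gene_id: g.model.stop_codon_pos for g in trome.genes}
        df = sim.ribo
        short = df[classify_sizes(df["length"]) == "short"]
        rel3 = short["end3"] - short["gene_id"].map(stops)
        assert len(short) == 20_000
        assert rel3.between(0, 2).all()

    def test_no_cleavage_leaves_only_ire_site_shorts(self):
        cfg = SimulationConfig(
            n_genes=20, depth=20_000, race_depth=100, seed=2,
            model="none", cleavage_rate=0.0, ire1_rate=0.2,
        )
        trome = simulate_transcriptome(cfg)
        sim = simulate_reads(trome, cfg)
        df = sim.ribo
        short = df[classify_sizes(df["length"]) == "short"]
        ire = trome.genes[0]
        assert (short["gene_id"] == ire.model.gene_id).all()
        assert (short["end3"] == ire.ire1_site).all()

    def test_gstall_automaton_on_designed_sequence(self):
        # one G five nt upstream of the stop, nothing else; every cut lands
        # 5 nt downstream and trimming must halt exactly on the G
        cfg = SimulationConfig(
            n_genes=2, depth=5000, race_depth=100, seed=6,
            model="model2_runon", cleavage_rate=1.0, g_stall_prob=1.0,
            intermediate_capture_prob=0.0, ire1_rate=0.0,
            cleavage_offset_law={5: 1.0}, trailing_gap_codons=(10, 10),
            termination_rate=0.0,
        )
        trome = simulate_transcriptome(cfg)
        g = trome.genes[1]
        stop = g.model.stop_codon_pos
        seq = ["A"] * g.model.spliced_length
        seq[stop:stop + 3] = list("TAA")
        seq[stop - 5] = "G"
        g.sequence = "".join(seq)
        sim = simulate_reads(trome, cfg)
        ends = sim.truth.loc[sim.truth["gene_id"] == g.model.gene_id, "end_rel"]
        assert set(ends) == {-5}
        assert (sim.truth.loc[sim.truth["gene_id"] == g.model.gene_id, "nuclease"] == "exosome").all()

    def test_intermediates_share_end3_and_step_5p_by_codons(self):
        cfg = SimulationConfig(
            n_genes=10, depth=10_000, race_depth=100, seed=8,
            model="model2_runon", cleavage_rate=1.0,
            intermediate_capture_prob=1.0, ire1_rate=0.0,
            cleavage_offset_law={0: 1.0}, termination_rate=0.0,
        )
        trome = simulate_transcriptome(cfg)
        sim = simulate_reads(trome, cfg)
        stops = {g.model.gene_id: g.model.stop_codon_pos for g in trome.genes}
        rel3 = sim.ribo["end3"] - sim.ribo["gene_id"].map(stops)
        assert (rel3 == 0).all()
        assert set(sim.ribo["length"]) == {19, 22, 25}

    def test_chemistry_map_changes_membership_not_positions(self):
        base = dict(n_genes=15, depth=2000, race_depth=8000, seed=12, ire1_rate=0.3)
        cfg1 = SimulationConfig(**base)
        cfg2 = SimulationConfig(
            **base, chemistry_map={"smg6": "OH", "exosome": "OH", "ire1": "OH"}
        )
        trome = simulate_transcriptome(cfg1)
        a = simulate_reads(trome, cfg1)
        b = simulate_reads(trome, cfg2)
        cols = ["gene_id", "end5", "end3", "length"]
        pd.testing.assert_frame_equal(a.race_plus_pnk[cols], b.race_plus_pnk[cols])
        # all-OH map: nothing is dropped from the -PNK library
        assert len(b.race_minus_pnk) == len(b.race_plus_pnk)
        assert len(a.race_minus_pnk) < len(a.race_plus_pnk)

    def test_out_of_bounds_cuts_resampled_or_clamped(self):
        cfg = SimulationConfig(
            n_genes=3, depth=2000, race_depth=100, seed=13,
            model="model2_runon", cleavage_rate=1.0, ire1_rate=0.0,
            utr3_length=50, cleavage_offset_law={500: 1.0},
            readthrough_prob=1.0,
        )
        trome = simulate_transcriptome(cfg)
        sim = simulate_reads(trome, cfg)
        assert sim.resample_count > 0
        limits = {
            g.model.gene_id: g.model.spliced_length - 1 - g.model.stop_codon_pos
            for g in trome.genes
        }
        assert (sim.truth["end_rel"] <= sim.truth["gene_id"].map(limits)).all()
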