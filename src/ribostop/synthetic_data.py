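"""Mechanistic simulator of mRNA cleavage at stop codons and its footprints.

Two competing mechanisms can explain the accumulation of short (15-18 nt)
ribosome footprints whose 3' ends sit in stop codons of decay-targeted
mRNAs:

* **model1_Asite** - the endonuclease (an SMG-6-like PIN domain) cuts
  directly in the ribosomal A-site over the stop codon.  Short footprints
  appear immediately at the stop; no other species is predicted.
* **model2_runon** - the endonuclease cuts at or downstream of the stop;
  the cytoplasmic exosome then trims the new 3' end 5'-ward (pausing at
  guanosines), and a trailing ribosome translates up to the truncated end
  and stalls there.  Because the ribosome's mRNA entry tunnel shields the
  last ``downstream_protect`` nucleotides from RNase during footprinting,
  a ribosome still approaching the end leaves *intermediate* footprints:
  same 3' end, 5' ends receding in 3-nt codon steps (lengths 25/22/19 under
  the default geometry), before collapsing to the stalled 15-18 nt species.

The geometry is: ``full_footprint = max(stalled_range) + downstream_protect``
(28 = 18 + 10 by default).  Both mechanisms use metal-dependent nucleases
and therefore leave 3'-hydroxyl (OH) ends; a designated "IRE-1-like" gene
carries one fixed internal cleavage site with 3'-phosphate (P) chemistry,
mimicking a metal-independent control locus that distinguishes the two
3'-RACE protocols (+PNK captures OH and P ends, -PNK captures OH only).

Everything is driven by one integer seed: a fixed config yields
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readmodel import TranscriptModel

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_G = ord("G")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def default_offset_law(p: float = 0.5, max_offset: int = 12) -> dict[int, float]:
    """Cut-site law: point mass on the stop codon's first nt plus a
    geometric(p) tail downstream, truncated at ``max_offset`` and
    renormalized.  Offsets are relative to the stop's first nt."""
    law = {0: 0.5}
    for k in range(1, max_offset + 1):
        law[k] = 0.5 * (1 - p) ** (k - 1) * p
    z = sum(law.values())
    return {k: v / z for k, v in law.items()}


@dataclass
class SimulationConfig:
    """Geometry, rates, chemistry and seed for the synthetic generator.

    Probabilities are per mRNA molecule; ``depth``/``race_depth`` are the
    number of Ribo-seq and 3'-RACE reads sampled per library.
    """

    n_genes: int = 100
    cds_length_range: tuple[int, int] = (300, 600)
    utr3_length: int = 150
    expression_law: str = "uniform"          # or "lognormal"
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    gc_content: float = 0.42

    # footprint geometry (nt)
    full_footprint: int = 28
    downstream_protect: int = 10             # A-site -> mRNA entry tunnel
    stalled_range: tuple[int, int] = (15, 18)

    model: str = "model2_runon"              # model1_Asite | model2_runon | none
    cleavage_rate: float = 0.3
    cleavage_offset_law: dict[int, float] = field(default_factory=default_offset_law)
    g_stall_prob: float = 0.5
    intermediate_capture_prob: float = 0.02
    readthrough_prob: float = 0.0
    readthrough_frame: int = 0               # 0 or -1
    frame_jitter_prob: float = 0.05
    termination_rate: float = 0.05           # 21-nt empty-A-site reads, model-independent
    short_background_rate: float = 0.0
    ire1_rate: float = 0.01                  # internal P-chemistry site on one gene
    trailing_gap_codons: tuple[int, int] = (5, 15)
    chemistry_map: dict[str, str] = field(
        default_factory=lambda: {"smg6": "OH", "exosome": "OH", "ire1": "P"}
    )

    depth: int = 200_000
    race_depth: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.full_footprint != self.stalled_range[1] + self.downstream_protect:
            raise ConfigError(
                "geometry inconsistent: full_footprint must equal "
                "max(stalled_range) + downstream_protect "
                f"({self.full_footprint} != {self.stalled_range[1]} + {self.downstream_protect})"
            )
        if self.cds_length_range[0] < 2 * self.full_footprint:
            raise ConfigError("cds_length_range lower bound below 2x full_footprint")
        for name in (
            "cleavage_rate", "g_stall_prob", "intermediate_capture_prob",
            "readthrough_prob", "frame_jitter_prob", "termination_rate",
            "short_background_rate", "ire1_rate", "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if self.model not in ("model1_Asite", "model2_runon", "none"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.readthrough_frame not in (0, -1):
            raise ConfigError("readthrough_frame must be 0 or -1")
        z = sum(self.cleavage_offset_law.values())
        if abs(z - 1.0) > 1e-9:
            self.cleavage_offset_law = {k: v / z for k, v in self.cleavage_offset_law.items()}

    @property
    def intermediate_ladder(self) -> tuple[int, ...]:
        """A-site-to-end distances of capturable intermediates: the codon
        ladder starting one nt beyond the stalled maximum."""
        hi = self.stalled_range[1]
        return tuple(
            d for d in range(1, self.downstream_protect, 3)
            if hi + d < self.full_footprint
        )

    @classmethod
    def human_preset(cls, **overrides) -> "SimulationConfig":
        """Mammalian geometry: 31-nt full footprint, 13-nt entry-tunnel
        protection, which shifts the intermediate series 3 nt upstream."""
        kw = dict(full_footprint=31, downstream_protect=13)
        kw.update(overrides)
        return cls(**kw)


def footprint_length(a_site_to_end: int, config: SimulationConfig) -> int:
    """Protected fragment length for a ribosome whose A-site first nt is
    ``a_site_to_end`` nt upstream of the fragment 3' end.

    The entry tunnel shields min(a_site_to_end, downstream_protect) nt
    downstream of the A-site, so the length clamps at ``full_footprint``;
    at distance 0 the stalled maximum is returned (5' jitter down to the
    stalled minimum is applied separately at emission).
    """
    if a_site_to_end < 0:
        raise ValueError("a_site_to_end must be >= 0 (run-on past the end is handled by the sampler)")
    return min(config.full_footprint, config.stalled_range[1] + a_site_to_end)


@dataclass
class SimulatedGene:
    model: TranscriptModel
    sequence: str
    weight: float
    ire1_site: int | None = None             # transcript-space position, or None
    #: per-gene override of the cut-site law (offsets relative to the stop)
    cleavage_offset_law: dict[int, float] | None = None

    @property
    def seq_array(self) -> np.ndarray:
        arr = getattr(self, "_seq_arr", None)
        if arr is None:
            arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
            object.__setattr__(self, "_seq_arr", arr)
        return arr


@dataclass
class Transcriptome:
    genes: list[SimulatedGene]
    config: SimulationConfig

    def transcripts(self) -> dict[str, TranscriptModel]:
        return {g.model.gene_id: g.model for g in self.genes}

    def sequences(self) -> dict[str, str]:
        return {g.model.gene_id: g.sequence for g in self.genes}

    @property
    def weights(self) -> np.ndarray:
        w = np.array([g.weight for g in self.genes], float)
        return w / w.sum()

    @property
    def ire1_gene(self) -> SimulatedGene | None:
        for g in self.genes:
            if g.ire1_site is not None:
                return g
        return None


def simulate_transcriptome(config: SimulationConfig) -> Transcriptome:
    """Generate ``n_genes`` single-isoform transcripts with sequences and
    expression weights.

    CDS lengths are uniform multiples of 3 within ``cds_length_range``;
    each transcript is CDS plus a 3' UTR of ``utr3_length`` nt, carries a
    TAA stop codon, and lives on its own contig (named after the gene).
    Gene 1 is the IRE-1-like control locus with a fixed internal cleavage
    site 60 nt upstream of its stop.
    """
    rng = np.random.default_rng([config.seed, 17])
    lo, hi = config.cds_length_range
    codon_choices = np.arange(-(-lo // 3), hi // 3 + 1) * 3
    cds_lens = rng.choice(codon_choices, size=config.n_genes)

    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    if config.expression_law == "uniform":
        weights = np.ones(config.n_genes)
    elif config.expression_law == "lognormal":
        weights = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, config.n_genes)
    else:
        raise ConfigError(f"unknown expression_law {config.expression_law!r}")

    genes = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        cds_len = int(cds_lens[i])
        length = cds_len + config.utr3_length
        seq = rng.choice(_BASES, size=length, p=base_p)
        stop = cds_len - 3
        seq[stop:stop + 3] = np.frombuffer(b"TAA", dtype="S1")
        gid = f"g{i + 1:0{width}d}"
        tm = TranscriptModel(
            gene_id=gid, transcript_id=f"{gid}.t1", strand="+",
            cds_segments=((0, cds_len),), spliced_length=length,
            stop_codon_pos=stop, n_annotated_stops=1, cds_start_pos=0,
            chrom=gid, exon_segments=((0, length),),
        )
        genes.append(
            SimulatedGene(
                model=tm, sequence=seq.tobytes().decode(), weight=float(weights[i]),
                ire1_site=(stop - 60) if i == 0 else None,
            )
        )
    return Transcriptome(genes=genes, config=config)


@dataclass
class SimulatedReads:
    """Read tables plus the generator's ground truth.

    ``truth`` has one row per cleaved Ribo-seq molecule: the drawn cut
    offset, the 3' end after exosome trimming (both stop-relative), the
    nuclease that made the final end, and whether the trailing ribosome
    read through the stop.
    """

    ribo: pd.DataFrame
    race_plus_pnk: pd.DataFrame
    race_minus_pnk: pd.DataFrame
    truth: pd.DataFrame
    resample_count: int = 0


def _draw_from_law(law: Mapping[int, float], size: int, rng) -> np.ndarray:
    keys = np.fromiter(law.keys(), dtype=np.int64)
    probs = np.fromiter(law.values(), dtype=float)
    return rng.choice(keys, size=size, p=probs / probs.sum())


def _draw_cuts(trome: Transcriptome, gene_idx: np.ndarray, rng) -> tuple[np.ndarray, int]:
    """Cut offsets (stop-relative) per molecule; cuts past the transcript
    end are resampled (counted)."""
    cfg = trome.config
    n = len(gene_idx)
    c = np.empty(n, dtype=np.int64)
    resampled = 0
    by_gene: dict[int, np.ndarray] = {}
    for gi in np.unique(gene_idx):
        by_gene[gi] = np.flatnonzero(gene_idx == gi)
    for gi, idx in by_gene.items():
        gene = trome.genes[gi]
        law = gene.cleavage_offset_law or cfg.cleavage_offset_law
        draws = _draw_from_law(law, len(idx), rng)
        limit = gene.model.spliced_length - 1 - gene.model.stop_codon_pos
        bad = draws > limit
        tries = 0
        while bad.any() and tries < 100:
            resampled += int(bad.sum())
            draws[bad] = _draw_from_law(law, int(bad.sum()), rng)
            bad = draws > limit
            tries += 1
        draws[bad] = limit  # give up after 100 rounds; clamp
        c[idx] = draws
    return c, resampled


def _trim_end(seq: np.ndarray, stop: int, t0: int, boundary: int, g_stall: float, rng) -> int:
    """3'>5' exosome automaton: scan 5'-ward from the cut, halting at a G
    with probability ``g_stall`` and unconditionally at ``boundary`` (the
    trailing ribosome's protection edge)."""
    t = t0
    while t > boundary:
        if seq[t] == _G and rng.random() < g_stall:
            return t
        t -= 1
    return boundary


def simulate_reads(trome: Transcriptome, config: SimulationConfig | None = None) -> SimulatedReads:
    """Sample Ribo-seq and +/-PNK 3'-RACE libraries under the configured model.

    Ribo-seq background: elongating ribosomes (28-30 nt, uniform over the
    CDS) and terminating ribosomes (21-nt empty-A-site reads at the stop,
    emitted at ``termination_rate`` regardless of model).  Cleaved
    molecules emit the model-specific stall/intermediate species; 3'-RACE
    fragments mirror the truncated 3' ends, and the -PNK library drops
    phosphate-chemistry ends (they cannot be ligated without PNK).
    """
    cfg = config or trome.config
    rng_ribo = np.random.default_rng([cfg.seed, 1])
    rng_plus = np.random.default_rng([cfg.seed, 2])
    rng_minus = np.random.default_rng([cfg.seed, 3])
    rng_umi = np.random.default_rng([cfg.seed, 4])

    ribo, truth, n_resampled = _simulate_ribo(trome, cfg, rng_ribo)
    race_p = _simulate_race(trome, cfg, rng_plus, drop_phosphate=False)
    race_m = _simulate_race(trome, cfg, rng_minus, drop_phosphate=True)

    for df in (ribo, race_p, race_m):
        df["umi"] = _random_umis(len(df), rng_umi)
    if n_resampled:
        log.info("resampled %d cut sites beyond transcript ends", n_resampled)
    return SimulatedReads(
        ribo=ribo, race_plus_pnk=race_p, race_minus_pnk=race_m,
        truth=truth, resample_count=n_resampled,
    )


def _random_umis(n: int, rng) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, 8)).astype(np.uint8)
    ascii_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ascii_map[idx].view("S8").ravel().astype("U8")


def _simulate_ribo(trome: Transcriptome, cfg: SimulationConfig, rng):
    genes = trome.genes
    stops = np.array([g.model.stop_codon_pos for g in genes])
    cds_start = np.array([g.model.cds_start_pos for g in genes])
    cds_end = np.array([g.model.cds_end_pos for g in genes])
    n = cfg.depth

    gene_idx = rng.choice(len(genes), size=n, p=trome.weights)
    u_ire = rng.random(n)
    u_cleave = rng.random(n)
    ire_gi = 0 if (genes and genes[0].ire1_site is not None) else -1

    is_ire = (gene_idx == ire_gi) & (u_ire < cfg.ire1_rate)
    cleave_rate = 0.0 if cfg.model == "none" else cfg.cleavage_rate
    is_cleaved = ~is_ire & (u_cleave < cleave_rate)
    is_bg = ~is_ire & ~is_cleaved

    end5 = np.empty(n, dtype=np.int64)
    end3 = np.empty(n, dtype=np.int64)
    s_lo, s_hi = cfg.stalled_range
    anchor5 = cfg.full_footprint - cfg.downstream_protect - 3  # 5' span ahead of the A-site

    # --- background: termination / short background / elongating ----------
    bg_idx = np.flatnonzero(is_bg)
    u_bg = rng.random(len(bg_idx))
    g_bg = gene_idx[bg_idx]
    term = u_bg < cfg.termination_rate
    shortbg = ~term & (u_bg < cfg.termination_rate + cfg.short_background_rate)
    elong = ~term & ~shortbg

    end5[bg_idx[term]] = stops[g_bg[term]] - anchor5
    end3[bg_idx[term]] = stops[g_bg[term]] + 5

    for mask, lo, hi in ((shortbg, s_lo, s_hi), (elong, cfg.full_footprint, cfg.full_footprint + 2)):
        rows = bg_idx[mask]
        if not len(rows):
            continue
        L = rng.integers(lo, hi + 1, size=len(rows))
        gi = gene_idx[rows]
        span = cds_end[gi] - L - cds_start[gi]
        e5 = cds_start[gi] + (rng.random(len(rows)) * (span + 1)).astype(np.int64)
        end5[rows] = e5
        end3[rows] = e5 + L - 1

    # --- IRE-1-like internal stalls ---------------------------------------
    ire_idx = np.flatnonzero(is_ire)
    if len(ire_idx):
        site = genes[ire_gi].ire1_site
        L = rng.integers(s_lo, s_hi + 1, size=len(ire_idx))
        end3[ire_idx] = site
        end5[ire_idx] = site - L + 1

    # --- cleaved molecules -------------------------------------------------
    truth_rows = []
    n_res = 0
    cl_idx = np.flatnonzero(is_cleaved)
    if len(cl_idx):
        gi = gene_idx[cl_idx]
        if cfg.model == "model1_Asite":
            pos = rng.integers(0, 3, size=len(cl_idx))
            L = rng.integers(s_lo, s_hi + 1, size=len(cl_idx))
            e3 = stops[gi] + pos
            end3[cl_idx] = e3
            end5[cl_idx] = e3 - L + 1
            for k in range(len(cl_idx)):
                truth_rows.append((genes[gi[k]].model.gene_id, int(pos[k]), int(pos[k]), "smg6", False))
        else:  # model2_runon
            c, n_res = _draw_cuts(trome, gi, rng)
            is_rt = rng.random(len(cl_idx)) < cfg.readthrough_prob
            u_cap = rng.random(len(cl_idx))
            ladder = cfg.intermediate_ladder
            gaps = rng.integers(cfg.trailing_gap_codons[0], cfg.trailing_gap_codons[1] + 1, size=len(cl_idx))
            for k in range(len(cl_idx)):
                g = genes[gi[k]]
                stop = int(stops[gi[k]])
                t0 = stop + int(c[k])
                row = cl_idx[k]
                if is_rt[k]:
                    t = t0  # the readthrough ribosome blocks the exosome
                    nuclease = "smg6"
                    _emit_runon(row, end5, end3, g, stop, t, cfg, rng, u_cap[k], ladder, frame_locked=True)
                else:
                    if c[k] > 0:
                        boundary = max(int(cds_start[gi[k]]), stop - 3 * int(gaps[k]) + 2 + cfg.downstream_protect)
                        t = _trim_end(g.seq_array, stop, t0, boundary, cfg.g_stall_prob, rng)
                    else:
                        t = t0
                    nuclease = "smg6" if t == t0 else "exosome"
                    if t > stop + 2:
                        # trimming halted (at a G) before reaching the stop:
                        # the terminating ribosome is unaffected -> 21-nt read
                        end5[row] = stop - anchor5
                        end3[row] = stop + 5
                    else:
                        _emit_runon(row, end5, end3, g, stop, t, cfg, rng, u_cap[k], ladder, frame_locked=False)
                truth_rows.append((g.model.gene_id, int(c[k]), int(t - stop), nuclease, bool(is_rt[k])))

    gene_ids = np.array([g.model.gene_id for g in genes])
    df = pd.DataFrame(
        {
            "gene_id": gene_ids[gene_idx],
            "end5": end5,
            "end3": end3,
            "length": end3 - end5 + 1,
            "chemistry": "unknown",
            "umi": "",
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "cut_rel", "end_rel", "nuclease", "readthrough"])
    return df, truth, n_res


def _emit_runon(row, end5, end3, gene, stop, t, cfg, rng, u_cap, ladder, frame_locked):
    """Emit the footprint of a trailing ribosome that ran to truncated end ``t``."""
    s_lo, s_hi = cfg.stalled_range
    if ladder and u_cap < cfg.intermediate_capture_prob:
        d = int(ladder[rng.integers(0, len(ladder))])
        L = cfg.stalled_range[1] + d
        end3[row] = t
        end5[row] = t - L + 1
        return
    if frame_locked:
        f = cfg.readthrough_frame
        a = stop + f + 3 * ((t - stop - f) // 3)
        e5 = a - (cfg.full_footprint - cfg.downstream_protect - 3)
        if rng.random() < cfg.frame_jitter_prob:
            e5 += 1
        end5[row] = e5
        end3[row] = t
    else:
        L = int(rng.integers(s_lo, s_hi + 1))
        end3[row] = t
        end5[row] = t - L + 1


def _simulate_race(trome: Transcriptome, cfg: SimulationConfig, rng, *, drop_phosphate: bool):
    """One 3'-RACE library: fragment 3' ends mirror molecule 3' ends."""
    genes = trome.genes
    stops = np.array([g.model.stop_codon_pos for g in genes])
    lengths = np.array([g.model.spliced_length for g in genes])
    cds_start = np.array([g.model.cds_start_pos for g in genes])
    n = cfg.race_depth

    gene_idx = rng.choice(len(genes), size=n, p=trome.weights)
    u_ire = rng.random(n)
    u_cleave = rng.random(n)
    ire_gi = 0 if (genes and genes[0].ire1_site is not None) else -1

    is_ire = (gene_idx == ire_gi) & (u_ire < cfg.ire1_rate)
    cleave_rate = 0.0 if cfg.model == "none" else cfg.cleavage_rate
    is_cleaved = ~is_ire & (u_cleave < cleave_rate)

    end3 = np.empty(n, dtype=np.int64)
    nuclease = np.full(n, "intact", dtype=object)

    end3[~is_ire & ~is_cleaved] = lengths[gene_idx[~is_ire & ~is_cleaved]] - 1
    if is_ire.any():
        end3[is_ire] = genes[ire_gi].ire1_site
        nuclease[is_ire] = "ire1"

    cl_idx = np.flatnonzero(is_cleaved)
    if len(cl_idx):
        gi = gene_idx[cl_idx]
        if cfg.model == "model1_Asite":
            end3[cl_idx] = stops[gi] + rng.integers(0, 3, size=len(cl_idx))
            nuclease[cl_idx] = "smg6"
        else:
            c, _ = _draw_cuts(trome, gi, rng)
            is_rt = rng.random(len(cl_idx)) < cfg.readthrough_prob
            gaps = rng.integers(cfg.trailing_gap_codons[0], cfg.trailing_gap_codons[1] + 1, size=len(cl_idx))
            for k in range(len(cl_idx)):
                g = genes[gi[k]]
                stop = int(stops[gi[k]])
                t0 = stop + int(c[k])
                if c[k] > 0 and not is_rt[k]:
                    boundary = max(int(cds_start[gi[k]]), stop - 3 * int(gaps[k]) + 2 + cfg.downstream_protect)
                    t = _trim_end(g.seq_array, stop, t0, boundary, cfg.g_stall_prob, rng)
                else:
                    t = t0
                end3[cl_idx[k]] = t
                nuclease[cl_idx[k]] = "smg6" if t == t0 else "exosome"

    chem = np.array([
        "OH" if nz == "intact" else cfg.chemistry_map.get(nz, "OH") for nz in nuclease
    ], dtype=object)
    end5 = np.maximum(0, end3 - 59)
    gene_ids = np.array([g.model.gene_id for g in genes])
    df = pd.DataFrame(
        {
            "gene_id": gene_ids[gene_idx],
            "end5": end5,
            "end3": end3,
            "length": end3 - end5 + 1,
            "chemistry": chem,
            "umi": "",
        }
    )
    if drop_phosphate:
        df = df[df["chemistry"] != "P"].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# writers


def write_transcriptome(trome: Transcriptome, gff_path: str | Path, fasta_path: str | Path) -> None:
    """Write the simulated annotation (GFF3) and sequences (FASTA); each
    gene sits on its own contig.  Headers are seed-stamped."""
    cfg = trome.config
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        gff.write(f"#ribostop-simulation seed={cfg.seed}\n")
        for g in trome.genes:
            tm = g.model
            L = tm.spliced_length
            cds_end = tm.cds_end_pos
            gid, tid = tm.gene_id, tm.transcript_id
            gff.write(f"{tm.chrom}\tribostop\tgene\t1\t{L}\t.\t+\t.\tID={gid}\n")
            gff.write(f"{tm.chrom}\tribostop\tmRNA\t1\t{L}\t.\t+\t.\tID={tid};Parent={gid}\n")
            gff.write(f"{tm.chrom}\tribostop\texon\t1\t{L}\t.\t+\t.\tID={tid}.e1;Parent={tid}\n")
            gff.write(f"{tm.chrom}\tribostop\tCDS\t1\t{cds_end}\t.\t+\t0\tID={tid}.c1;Parent={tid}\n")
    with open(fasta_path, "w") as fa:
        for g in trome.genes:
            fa.write(f">{g.model.gene_id}\n")
            for i in range(0, len(g.sequence), 80):
                fa.write(g.sequence[i:i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader for the simulator's own output."""
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(";") or not line.strip():
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}
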