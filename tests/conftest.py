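import numpy as np
import pandas as pd
import pytest

from ribostop.readmodel import READ_TABLE_COLUMNS, TranscriptModel
from ribostop.synthetic_data import SimulationConfig, simulate_reads, simulate_transcriptome


def make_tm(gene_id="gX", cds_len=90, utr3=30, n_stops=1):
    """Single-exon plus-strand transcript: CDS starts at 0, stop codon at
    cds_len-3, 3' UTR of ``utr3`` nt."""
    return TranscriptModel(
        gene_id=gene_id, transcript_id=f"{gene_id}.t", strand="+",
        cds_segments=((0, cds_len),), spliced_length=cds_len + utr3,
        stop_codon_pos=cds_len - 3, n_annotated_stops=n_stops,
        cds_start_pos=0, chrom=gene_id, exon_segments=((0, cds_len + utr3),),
    )


def reads_frame(rows):
    """Rows of (gene_id, end5, end3[, chemistry[, umi]]) -> read-ends frame."""
    full = []
    for r in rows:
        g, e5, e3 = r[0], r[1], r[2]
        chem = r[3] if len(r) > 3 else "unknown"
        umi = r[4] if len(r) > 4 else ""
        full.append((g, e5, e3, e3 - e5 + 1, chem, umi))
    return pd.DataFrame(full, columns=READ_TABLE_COLUMNS)


@pytest.fixture(scope="session")
def small_sim():
    """A modest model2 simulation shared by read-only tests."""
    cfg = SimulationConfig(n_genes=40, depth=40_000, race_depth=30_000, seed=5)
    trome = simulate_transcriptome(cfg)
    sim = simulate_reads(trome, cfg)
    return cfg, trome, sim


TOY_GFF = """##gff-version 3
chr1\ttoy\tgene\t101\t300\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t101\t300\t.\t+\t.\tID=tA;Parent=geneA
chr1\ttoy\texon\t101\t300\t.\t+\t.\tID=tA.e1;Parent=tA
chr1\ttoy\tCDS\t101\t200\t.\t+\t0\tID=tA.c1;Parent=tA
chr2\ttoy\tgene\t101\t300\t.\t-\t.\tID=geneB
chr2\ttoy\tmRNA\t101\t300\t.\t-\t.\tID=tB;Parent=geneB
chr2\ttoy\texon\t101\t300\t.\t-\t.\tID=tB.e1;Parent=tB
chr2\ttoy\tCDS\t201\t300\t.\t-\t0\tID=tB.c1;Parent=tB
chr3\ttoy\tgene\t101\t400\t.\t+\t.\tID=geneC
chr3\ttoy\tmRNA\t101\t400\t.\t+\t.\tID=tC1;Parent=geneC
chr3\ttoy\texon\t101\t400\t.\t+\t.\tID=tC1.e1;Parent=tC1
chr3\ttoy\tCDS\t101\t200\t.\t+\t0\tID=tC1.c1;Parent=tC1
chr3\ttoy\tmRNA\t101\t400\t.\t+\t.\tID=tC2;Parent=geneC
chr3\ttoy\texon\t101\t400\t.\t+\t.\tID=tC2.e1;Parent=tC2
chr3\ttoy\tCDS\t101\t260\t.\t+\t0\tID=tC2.c1;Parent=tC2
chr4\ttoy\tCDS\t10\t60\t.\t+\t0\tID=orphan.c1;Parent=missing_t
"""


@pytest.fixture(scope="session")
def toy_gff_text():
    return TOY_GFF
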