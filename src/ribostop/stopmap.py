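"""Gene-level positional analyses at stop codons.

Two views of where decay truncations leave ribosomes on individual
genes: (i) a heatmap of per-gene cumulative distributions (CDFs) of
short-footprint 3' ends within a 100-nt window centered on the stop,
with genes ordered by the position where the CDF first reaches 50%; and
(ii) the reading-frame composition of footprints downstream of the stop,
which distinguishes translating (readthrough) ribosomes from noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readmodel import TranscriptModel, annotate_relative

#: "100 nt window centered on the stop codon": relative positions -50..+49,
#: with 0 the first nt of the stop codon.
HEATMAP_WINDOW = (-50, 49)


@dataclass
class GeneEndCDF:
    gene_id: str
    window: tuple[int, int]
    positions: np.ndarray
    cdf: np.ndarray
    half_point: int          # smallest position with cdf >= 0.5
    n_reads: int


@dataclass
class FrameFractions:
    """Fractions of downstream reads whose 5' ends fall in frames 0/+1/+2
    relative to the CDS reading frame.  ``n_reads == 0`` flags an empty
    result (fractions are NaN, not an exception)."""

    fractions: tuple[float, float, float]
    n_reads: int

    @property
    def empty(self) -> bool:
        return self.n_reads == 0


def _short_end3(reads, transcripts, size_class):
    df = reads if "rel3" in reads.columns else annotate_relative(reads, transcripts)
    if size_class is not None:
        df = df[df["size_class"] == size_class]
    return df


def select_heatmap_genes(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    *,
    min_reads: int = 50,
    window: tuple[int, int] = HEATMAP_WINDOW,
    size_class: str | None = "short",
) -> list[str]:
    """Genes with >= ``min_reads`` 3' ends inside the window and a single
    annotated stop codon across isoforms."""
    df = _short_end3(reads, transcripts, size_class)
    lo, hi = window
    counts = df[(df["rel3"] >= lo) & (df["rel3"] <= hi)].groupby("gene_id").size()
    keep = [
        g for g, c in counts.items()
        if c >= min_reads and transcripts[g].n_annotated_stops == 1
    ]
    return sorted(keep)


def gene_cdf(
    reads: pd.DataFrame,
    gene_id: str,
    transcripts: Mapping[str, TranscriptModel],
    *,
    window: tuple[int, int] = HEATMAP_WINDOW,
    size_class: str | None = "short",
) -> GeneEndCDF:
    """Cumulative fraction of a gene's read 3' ends across the window."""
    df = _short_end3(reads, transcripts, size_class)
    lo, hi = window
    r = df.loc[(df["gene_id"] == gene_id) & (df["rel3"] >= lo) & (df["rel3"] <= hi), "rel3"]
    n = len(r)
    if n == 0:
        raise ValueError(f"gene {gene_id}: no in-window 3' ends (selection should prevent this)")
    positions = np.arange(lo, hi + 1)
    counts = np.zeros(len(positions))
    np.add.at(counts, (r.to_numpy() - lo).astype(int), 1)
    cdf = np.cumsum(counts) / n
    half = int(positions[np.argmax(cdf >= 0.5)])
    return GeneEndCDF(
        gene_id=gene_id, window=window, positions=positions, cdf=cdf,
        half_point=half, n_reads=n,
    )


def order_genes(cdfs: Sequence[GeneEndCDF]) -> list[str]:
    """Ascending half-point order; ties broken lexicographically by gene id."""
    if not cdfs:
        raise ValueError("no CDFs supplied")
    return [c.gene_id for c in sorted(cdfs, key=lambda c: (c.half_point, c.gene_id))]


def cdf_matrix(cdfs: Sequence[GeneEndCDF]) -> pd.DataFrame:
    """Genes x positions CDF matrix in heatmap (half-point) order."""
    order = order_genes(cdfs)
    by_id = {c.gene_id: c for c in cdfs}
    first = by_id[order[0]]
    return pd.DataFrame(
        [by_id[g].cdf for g in order], index=order, columns=first.positions
    )


def half_point_table(cdfs: Sequence[GeneEndCDF]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.half_point, c.n_reads) for c in sorted(cdfs, key=lambda c: (c.half_point, c.gene_id))],
        columns=["gene_id", "half_point", "n_reads"],
    )


def frame_fractions(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    *,
    size_class: str | None = "short",
    anchor_threshold: int = 2,
) -> FrameFractions:
    """Frame composition of reads strictly downstream of the stop codon.

    A read qualifies when its 3' end is beyond ``stop + anchor_threshold``
    (default: past the last stop-codon nt).  Frame is the read's 5'-end
    offset modulo 3 relative to the CDS reading frame (the stop codon is
    in frame 0 by construction).
    """
    df = _short_end3(reads, transcripts, size_class)
    down = df[df["rel3"] > anchor_threshold]
    n = len(down)
    if n == 0:
        return FrameFractions(fractions=(float("nan"),) * 3, n_reads=0)
    frames = np.mod(down["rel5"].to_numpy(), 3)
    f = tuple(float((frames == k).sum()) / n for k in range(3))
    return FrameFractions(fractions=f, n_reads=n)
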