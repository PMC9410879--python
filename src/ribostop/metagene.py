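"""Stop-codon-anchored metagene profiles of normalized read density.

Each gene's per-position counts are divided by its length-normalized CDS
read count (``cds_total / cds_length``), so a gene with perfectly uniform
coverage contributes 1.0 at every position and highly expressed genes do
not dominate the average.  The CDS denominator uses *all* supplied reads
(every size class) as the expression proxy, while the profile itself is
restricted to the requested size class; positions a gene's transcript
does not cover are excluded from that gene's contribution rather than
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .readmodel import TranscriptModel, annotate_relative


@dataclass
class MetageneProfile:
    anchor: str                    # "5p" or "3p"
    size_class: str
    gene_set_label: str
    window: tuple[int, int]
    positions: np.ndarray
    density: np.ndarray            # mean normalized density per position
    n_genes: int
    genes_per_position: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "density": self.density,
                "n_genes": self.genes_per_position,
                "size_class": self.size_class,
                "gene_set": self.gene_set_label,
            }
        )


def gene_density(counts: np.ndarray, cds_total: float, cds_length: int) -> np.ndarray:
    """Normalized density: ``count(p) / (cds_total / cds_length)``.

    ``cds_total`` must be positive; callers exclude zero-coverage genes
    before ever reaching this point.
    """
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    if cds_total <= 0:
        raise ValueError("cds_total must be positive (gene should have been excluded)")
    return np.asarray(counts, dtype=float) * (cds_length / cds_total)


def metagene_profile(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    *,
    size_class: str = "short",
    anchor: str = "3p",
    window: tuple[int, int] = (-50, 50),
    min_reads: int = 5,
    gene_set: Iterable[str] | None = None,
    gene_set_label: str = "all",
) -> MetageneProfile:
    """Average normalized read density around the stop codon.

    Genes enter the average when their all-class CDS read count reaches
    ``min_reads``; the per-position mean is taken over the genes whose
    transcript covers that position.  Raises if the gene set is empty
    after filtering.
    """
    if anchor not in ("5p", "3p"):
        raise ValueError("anchor must be '5p' or '3p'")
    df = reads if "rel3" in reads.columns else annotate_relative(reads, transcripts)
    if gene_set is not None:
        gene_set = set(gene_set)
        df = df[df["gene_id"].isin(gene_set)]
        if df.empty:
            raise ValueError(f"gene set {gene_set_label!r} matched no reads")

    lo, hi = window
    positions = np.arange(lo, hi + 1)
    rel = df["rel3"] if anchor == "3p" else df["rel5"]

    # all-class CDS totals: anchored end within [cds_start, cds_end)
    cds_tot = {}
    for gid, sub in df.groupby("gene_id", sort=False):
        tm = transcripts.get(gid)
        if tm is None:
            continue
        r = (sub["rel3"] if anchor == "3p" else sub["rel5"]) + tm.stop_codon_pos
        cds_tot[gid] = int(((r >= tm.cds_start_pos) & (r < tm.cds_end_pos)).sum())

    sub = df[df["size_class"] == size_class]
    rel_sub = (sub["rel3"] if anchor == "3p" else sub["rel5"]).to_numpy()
    gene_col = sub["gene_id"].to_numpy()

    total = np.zeros(len(positions))
    n_cover = np.zeros(len(positions), dtype=int)
    n_genes = 0
    for gid, tot in cds_tot.items():
        tm = transcripts[gid]
        if tot < min_reads:
            continue
        n_genes += 1
        mask = gene_col == gid
        r = rel_sub[mask]
        counts = np.zeros(len(positions))
        inw = (r >= lo) & (r <= hi)
        np.add.at(counts, (r[inw] - lo).astype(int), 1)
        dens = gene_density(counts, tot, tm.cds_length)
        covered = (positions + tm.stop_codon_pos >= 0) & (
            positions + tm.stop_codon_pos < tm.spliced_length
        )
        total[covered] += dens[covered]
        n_cover += covered
    if n_genes == 0:
        raise ValueError(f"no genes pass min_reads={min_reads} for gene set {gene_set_label!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(n_cover > 0, total / np.maximum(n_cover, 1), 0.0)
    return MetageneProfile(
        anchor=anchor, size_class=size_class, gene_set_label=gene_set_label,
        window=window, positions=positions, density=density,
        n_genes=n_genes, genes_per_position=n_cover,
    )
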