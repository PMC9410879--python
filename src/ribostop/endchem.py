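"""3'-end chemistry calls from +/-PNK 3'-RACE libraries, and 3'-end base
composition near stop codons.

Metal-dependent nucleases (SMG-6-like PIN domains, the exosome) leave
3'-hydroxyl (OH) ends that ligate directly in 3'-RACE; metal-independent
nucleases leave 3'-phosphate (P) ends that require prior PNK treatment.
Comparing a site's depth-normalized abundance between the -PNK (OH-only)
and +PNK (OH+P) libraries therefore classifies the chemistry of the
nuclease that made the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readmodel import TranscriptModel, annotate_relative

log = logging.getLogger(__name__)


@dataclass
class SiteChemistryCall:
    gene_id: str
    relative_position: int
    count_ohp: int           # +PNK library (OH + P ends)
    count_oh: int            # -PNK library (OH ends only)
    ratio: float             # depth-normalized oh / ohp
    call: str                # OH-dominant | P-dominant | indeterminate


def _site_counts(df, sites):
    key = df.groupby(["gene_id", "rel3"]).size()
    return {s: int(key.get(s, 0)) for s in sites}


def find_cleavage_sites(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    *,
    min_count: int = 50,
) -> list[tuple[str, int]]:
    """Candidate cleavage sites: (gene, stop-relative position) pairs that
    are local maxima of the 3'-end profile with at least ``min_count``
    reads, excluding the transcript's annotated 3' terminus."""
    df = reads if "rel3" in reads.columns else annotate_relative(reads, transcripts)
    out = []
    for gid, sub in df.groupby("gene_id", sort=True):
        tm = transcripts[gid]
        term_rel = tm.spliced_length - 1 - tm.stop_codon_pos
        counts = sub.groupby("rel3").size()
        for pos, c in counts.items():
            if c < min_count or pos == term_rel:
                continue
            if c >= counts.get(pos - 1, 0) and c >= counts.get(pos + 1, 0):
                out.append((gid, int(pos)))
    return out


def compare_libraries(
    oh_reads: pd.DataFrame,
    ohp_reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    sites: Sequence[tuple[str, int]] | None = None,
    *,
    min_site_reads: int = 10,
    oh_threshold: float = 0.5,
    p_threshold: float = 0.25,
) -> list[SiteChemistryCall]:
    """Classify 3'-end chemistry per site from the two RACE libraries.

    ``ratio = (count_oh / depth_oh) / (count_ohp / depth_ohp)`` with depth
    the library's total read count; an OH end appears equally in both
    libraries (ratio ~ 1) while a P end is absent from -PNK (ratio ~ 0).
    Calls: OH-dominant if ratio >= ``oh_threshold``, P-dominant if
    <= ``p_threshold``, else indeterminate; sites with fewer than
    ``min_site_reads`` combined reads are always indeterminate.  The
    thresholds are heuristics chosen to separate the simulated pure-OH
    and pure-P regimes with margin, not literature values.
    """
    oh = oh_reads if "rel3" in oh_reads.columns else annotate_relative(oh_reads, transcripts)
    ohp = ohp_reads if "rel3" in ohp_reads.columns else annotate_relative(ohp_reads, transcripts)
    depth_oh, depth_ohp = len(oh), len(ohp)
    if depth_oh == 0 or depth_ohp == 0:
        raise ValueError("zero total depth in one of the libraries")
    if sites is None:
        sites = find_cleavage_sites(ohp, transcripts, min_count=min_site_reads)
    c_oh = _site_counts(oh, sites)
    c_ohp = _site_counts(ohp, sites)
    calls = []
    for s in sites:
        a, b = c_oh[s], c_ohp[s]
        if b == 0:
            ratio = float("inf") if a > 0 else float("nan")
        else:
            ratio = (a / depth_oh) / (b / depth_ohp)
        if a + b < min_site_reads or not np.isfinite(ratio):
            call = "indeterminate"
        elif ratio >= oh_threshold:
            call = "OH-dominant"
        elif ratio <= p_threshold:
            call = "P-dominant"
        else:
            call = "indeterminate"
        calls.append(
            SiteChemistryCall(
                gene_id=s[0], relative_position=s[1],
                count_ohp=b, count_oh=a, ratio=ratio, call=call,
            )
        )
    return calls


def calls_to_frame(calls: Sequence[SiteChemistryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.gene_id, c.relative_position, c.count_ohp, c.count_oh, c.ratio, c.call)
            for c in calls
        ],
        columns=["gene_id", "relative_position", "count_ohp", "count_oh", "ratio", "call"],
    )


def end_base_composition(
    reads: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    *,
    max_distance: int = 10,
) -> pd.Series:
    """Base frequencies at read 3' ends within ``max_distance`` nt of the
    stop codon, over {A, C, G, T} and summing to 1.

    Guanosine enrichment over the transcriptome's positional base content
    is the fingerprint of exosome stalling at G.  Reads whose 3' end lies
    outside the available sequence are skipped with a logged count.
    """
    df = reads if "rel3" in reads.columns else annotate_relative(reads, transcripts)
    near = df[df["rel3"].abs() <= max_distance]
    counts = {b: 0 for b in "ACGT"}
    skipped = 0
    for gid, sub in near.groupby("gene_id", sort=False):
        seq = sequences.get(gid)
        if seq is None:
            skipped += len(sub)
            continue
        for e3 in sub["end3"].to_numpy():
            if 0 <= e3 < len(seq):
                base = seq[e3].upper().replace("U", "T")
                if base in counts:
                    counts[base] += 1
            else:
                skipped += 1
    if skipped:
        log.warning("skipped %d read ends outside sequence bounds", skipped)
    total = sum(counts.values())
    if total == 0:
        return pd.Series({b: float("nan") for b in "ACGT"})
    return pd.Series({b: c / total for b, c in counts.items()})


def positional_base_content(
    transcripts: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    *,
    max_distance: int = 10,
) -> pd.Series:
    """Background base frequencies over all transcript positions within
    ``max_distance`` of the stop codon (for contrast with
    :func:`end_base_composition`)."""
    counts = {b: 0 for b in "ACGT"}
    for gid, tm in transcripts.items():
        seq = sequences.get(gid)
        if seq is None:
            continue
        stop = tm.stop_codon_pos
        for pos in range(max(0, stop - max_distance), min(len(seq), stop + max_distance + 1)):
            base = seq[pos].upper().replace("U", "T")
            if base in counts:
                counts[base] += 1
    total = sum(counts.values())
    return pd.Series({b: c / total for b, c in counts.items()})
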