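"""Transcript models, read records and stop-codon-relative coordinates.

Everything downstream of alignment runs in *transcript space*: 0-based
positions along the spliced transcript, 5'->3' regardless of genomic
strand.  The single anchor shared by all analyses is the first nucleotide
of the annotated stop codon; relative position 0 means "on that
nucleotide", negative means upstream.

The on-disk interchange format is the *read-ends table*: a tab-separated
file (gzip-transparent) with columns ``gene_id end5 end3 length chemistry
umi`` and ``#``-prefixed metadata lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

READ_TABLE_COLUMNS = ["gene_id", "end5", "end3", "length", "chemistry", "umi"]

#: inclusive length bounds of the gel size-selected footprint classes
SIZE_CLASS_BOUNDS = {"short": (15, 18), "mid": (19, 26), "long": (28, 30)}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


def classify_size(length: int) -> str:
    """Map a fragment length (nt) to its footprint size class.

    15-18 nt -> ``short`` (stalled at a truncated 3' end), 19-26 nt ->
    ``mid`` (includes the 21-nt empty-A-site and the 19/22/25-nt
    intermediate species), 28-30 nt -> ``long`` (elongating); anything
    else -> ``other``.
    """
    for name, (lo, hi) in SIZE_CLASS_BOUNDS.items():
        if lo <= length <= hi:
            return name
    return "other"


def classify_sizes(lengths) -> np.ndarray:
    """Vectorized :func:`classify_size` over an array-like of lengths."""
    lengths = np.asarray(lengths)
    out = np.full(lengths.shape, "other", dtype=object)
    for name, (lo, hi) in SIZE_CLASS_BOUNDS.items():
        out[(lengths >= lo) & (lengths <= hi)] = name
    return out


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with CDS bounds, in transcript coordinates.

    ``cds_segments`` are genomic 0-based half-open intervals ordered
    5'->3' in transcript orientation; the CDS is taken to *include* the
    stop codon, so ``stop_codon_pos`` (transcript space, first nt of the
    stop) equals ``cds_start_pos + cds_length - 3``.
    """

    gene_id: str
    transcript_id: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    spliced_length: int
    stop_codon_pos: int
    n_annotated_stops: int = 1
    cds_start_pos: int = 0
    chrom: str = ""
    #: genomic exon intervals (0-based half-open) ordered 5'->3' in
    #: transcript orientation; empty means "CDS segments are the exons"
    exon_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.stop_codon_pos <= self.spliced_length - 3):
            raise ValueError(
                f"{self.transcript_id}: stop_codon_pos {self.stop_codon_pos} "
                f"outside [0, {self.spliced_length - 3}]"
            )
        if self.n_annotated_stops < 1:
            raise ValueError("n_annotated_stops must be >= 1")
        for (a, b), (c, d) in zip(self.cds_segments, self.cds_segments[1:]):
            if b > c and not (d <= a):  # neither strictly before nor after
                raise ValueError(f"{self.transcript_id}: overlapping CDS segments")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_segments)

    @property
    def cds_end_pos(self) -> int:
        """Transcript-space position one past the last CDS nt (stop included)."""
        return self.cds_start_pos + self.cds_length


@dataclass(frozen=True)
class ReadRecord:
    """One deduplicated footprint / 3'-RACE fragment in transcript space."""

    gene_id: str
    end5: int
    end3: int
    chemistry: str = "unknown"
    umi: str = ""

    def __post_init__(self):
        if self.end3 < self.end5:
            raise ValueError(f"end3 < end5 ({self.end3} < {self.end5})")

    @property
    def length(self) -> int:
        return self.end3 - self.end5 + 1

    @property
    def size_class(self) -> str:
        return classify_size(self.length)


# ---------------------------------------------------------------------------
# annotation parsing


def _build_exon_map(exons, strand):
    """Return list of (genomic_start, genomic_end, transcript_offset) in
    transcript order for 0-based half-open genomic intervals."""
    exons = sorted(exons)
    if strand == "-":
        exons = exons[::-1]
    out, off = [], 0
    for a, b in exons:
        out.append((a, b, off))
        off += b - a
    return out, off


def _genomic_to_transcript(exon_map, strand, gpos):
    """Transcript offset of genomic position ``gpos`` (0-based)."""
    for a, b, off in exon_map:
        if a <= gpos < b:
            return off + (gpos - a if strand == "+" else b - 1 - gpos)
    raise ValueError(f"genomic position {gpos} not in any exon")


def parse_annotation(source: str | Path, *, from_string: bool = False) -> list[TranscriptModel]:
    """Parse a GFF3/GTF annotation into :class:`TranscriptModel` objects.

    ``source`` is a path unless ``from_string`` is set, in which case it
    is the annotation text itself.  Transcripts lacking CDS features are
    skipped; CDS features whose parent transcript is absent are skipped
    with a logged warning.  ``n_annotated_stops`` counts distinct genomic
    stop-codon positions across each gene's isoforms.

    Minus-strand features are flipped so transcript coordinates always
    run 5'->3'.  The CDS is assumed to include the stop codon.
    """
    import gffutils

    text = source if from_string else Path(source).read_text()
    for i, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise AnnotationError(f"malformed feature at line {i}: expected 9 tab-separated fields")

    db = gffutils.create_db(
        text, ":memory:", from_string=True, force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    tx_types = {"mRNA", "transcript"}
    transcripts: dict[str, dict] = {}
    for t in db.all_features():
        if t.featuretype not in tx_types:
            continue
        exons = [(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
        cds = [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
        if not cds:
            continue
        if not exons:
            exons = list(cds)
        parents = list(db.parents(t, featuretype="gene"))
        gene_id = parents[0].id if parents else t.attributes.get("gene_id", [t.id])[0]
        transcripts[t.id] = dict(
            gene_id=gene_id, strand=t.strand, chrom=t.seqid, exons=exons, cds=cds,
        )

    known_parents = set(transcripts)
    orphan = 0
    for c in db.features_of_type("CDS"):
        pids = c.attributes.get("Parent", []) or c.attributes.get("transcript_id", [])
        if pids and not any(p in known_parents for p in pids):
            orphan += 1
    if orphan:
        log.warning("skipped %d CDS features with no parent transcript", orphan)

    # distinct genomic stop positions per gene (first nt of the stop codon)
    gene_stops: dict[str, set] = {}
    models_raw = []
    for tid, info in transcripts.items():
        strand = info["strand"]
        exon_map, length = _build_exon_map(info["exons"], strand)
        cds = sorted(info["cds"])
        cds_tx = cds[::-1] if strand == "-" else cds
        if strand == "+":
            cds_start_g, stop_first_g = cds[0][0], cds[-1][1] - 3
        else:
            cds_start_g, stop_first_g = cds[-1][1] - 1, cds[0][0] + 2
        cds_start = _genomic_to_transcript(exon_map, strand, cds_start_g)
        stop_pos = _genomic_to_transcript(exon_map, strand, stop_first_g)
        gene_stops.setdefault(info["gene_id"], set()).add((info["chrom"], strand, stop_first_g))
        exons_tx = sorted(info["exons"])
        if strand == "-":
            exons_tx = exons_tx[::-1]
        models_raw.append(
            dict(
                gene_id=info["gene_id"], transcript_id=tid, strand=strand,
                cds_segments=tuple(tuple(s) for s in cds_tx),
                spliced_length=length, stop_codon_pos=stop_pos,
                cds_start_pos=cds_start, chrom=info["chrom"],
                exon_segments=tuple(tuple(s) for s in exons_tx),
            )
        )

    return [
        TranscriptModel(n_annotated_stops=len(gene_stops[m["gene_id"]]), **m)
        for m in models_raw
    ]


def by_gene(transcripts: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Index transcripts by gene, keeping the longest-CDS isoform per gene."""
    out: dict[str, TranscriptModel] = {}
    for tm in transcripts:
        cur = out.get(tm.gene_id)
        if cur is None or tm.cds_length > cur.cds_length:
            out[tm.gene_id] = tm
    return out


# ---------------------------------------------------------------------------
# read ingestion


def collapse_umis(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates by exact (gene_id, end5, length, umi) match.

    The 3' end is implied by ``end5`` and ``length`` given how the UMI
    randomer sits on the adapter, so it is not part of the key.  Rows
    with an empty UMI cannot be deduplicated and are each retained, with
    a warning.  Output order is deterministic (gene, end5, length, umi).
    Idempotent.
    """
    df = reads.copy()
    if "length" not in df.columns:
        df["length"] = df["end3"] - df["end5"] + 1
    empty = df["umi"].astype(str) == ""
    n_empty = int(empty.sum())
    if n_empty:
        log.warning("%d reads with empty UMI retained without collapsing", n_empty)
    keyed = df[~empty].drop_duplicates(subset=["gene_id", "end5", "length", "umi"])
    out = pd.concat([keyed, df[empty]], ignore_index=True)
    return out.sort_values(
        ["gene_id", "end5", "length", "umi"], kind="mergesort"
    ).reset_index(drop=True)


def to_stop_relative(record: ReadRecord, tm: TranscriptModel, anchor: str = "3p") -> int:
    """Stop-codon-relative position of one read end.

    0 = anchored end on the first nt of the stop codon; negative =
    upstream.  ``anchor`` selects the 5' or 3' end.
    """
    if record.gene_id != tm.gene_id:
        raise ValueError(f"read gene {record.gene_id!r} does not match transcript {tm.gene_id!r}")
    end = record.end3 if anchor == "3p" else record.end5
    return end - tm.stop_codon_pos


def annotate_relative(reads: pd.DataFrame, transcripts: Mapping[str, TranscriptModel]) -> pd.DataFrame:
    """Add ``rel5``/``rel3`` stop-relative columns; drop reads on unknown genes."""
    stops = pd.Series({g: t.stop_codon_pos for g, t in transcripts.items()}, dtype="int64")
    known = reads["gene_id"].isin(stops.index)
    dropped = int((~known).sum())
    if dropped:
        log.warning("dropped %d reads on genes absent from the annotation", dropped)
    df = reads[known].copy()
    s = df["gene_id"].map(stops)
    df["rel5"] = df["end5"] - s
    df["rel3"] = df["end3"] - s
    if "size_class" not in df.columns:
        df["size_class"] = classify_sizes(df["length"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# read-ends table I/O


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a read-ends table (TSV, gzip-transparent, ``#`` comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "umi": str, "chemistry": str})
    df["umi"] = df["umi"].fillna("")
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["length"] != df["end3"] - df["end5"] + 1).any():
        raise ValueError(f"{path}: length column inconsistent with end5/end3")
    return df[READ_TABLE_COLUMNS + [c for c in df.columns if c not in READ_TABLE_COLUMNS]]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a read-ends table with ``#key=value`` metadata header lines."""
    path = Path(path)
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def records_to_frame(records: Iterable[ReadRecord]) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.end5, r.end3, r.length, r.chemistry, r.umi) for r in records
    ]
    return pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ReadRecord]:
    return [
        ReadRecord(r.gene_id, int(r.end5), int(r.end3), str(r.chemistry), str(r.umi))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# SAM/BAM ingestion


def load_alignments(
    path: str | Path,
    transcripts: Iterable[TranscriptModel],
    *,
    mapq_min: int = 10,
    umi_sep: str = "_",
) -> pd.DataFrame:
    """Project aligned reads onto spliced transcripts as a read-ends table.

    Alignments must be genomic (or to per-gene contigs); a read is kept
    only if every aligned block falls within the exons of a single
    transcript and its orientation matches that transcript's strand.
    Multi-mapping is excluded via ``MAPQ >= mapq_min`` as a uniqueness
    proxy.  The UMI is taken from the read name after the last
    ``umi_sep``.  Dropped-read counts are logged.
    """
    import pysam

    tx_by_chrom: dict[str, list] = {}
    for tm in transcripts:
        exons = tm.exon_segments or tm.cds_segments
        exon_map, _ = _build_exon_map(list(exons), tm.strand)
        tx_by_chrom.setdefault(tm.chrom, []).append((tm, exon_map))

    mode = "rb" if str(path).endswith(".bam") else "r"
    n_drop_mapq = n_drop_outside = n_drop_strand = 0
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < mapq_min:
                n_drop_mapq += 1
                continue
            hit = None
            for tm, exon_map in tx_by_chrom.get(aln.reference_name, []):
                try:
                    a = _genomic_to_transcript(exon_map, tm.strand, aln.reference_start)
                    b = _genomic_to_transcript(exon_map, tm.strand, aln.reference_end - 1)
                except ValueError:
                    continue
                if aln.is_reverse != (tm.strand == "-"):
                    n_drop_strand += 1
                    hit = None
                    break
                hit = (tm.gene_id, min(a, b), max(a, b))
                break
            if hit is None:
                n_drop_outside += 1
                continue
            umi = aln.query_name.rsplit(umi_sep, 1)[-1] if umi_sep in aln.query_name else ""
            rows.append((hit[0], hit[1], hit[2], hit[2] - hit[1] + 1, "unknown", umi))
    if n_drop_mapq or n_drop_outside or n_drop_strand:
        log.info(
            "alignment ingest: dropped %d low-MAPQ, %d outside-exon, %d antisense reads",
            n_drop_mapq, n_drop_outside, n_drop_strand,
        )
    return pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
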