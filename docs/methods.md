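# Methods

## Coordinate conventions

All analyses run in transcript space: 0-based positions along the
spliced transcript, 5′→3′ regardless of genomic strand.  Intervals in
files are 0-based half-open; GFF input is converted on parsing.  The
shared anchor is the first nucleotide of the annotated stop codon;
relative position 0 is that nucleotide, negative is upstream.  The CDS
is taken to include the stop codon, so the stop's first nucleotide is
`cds_end − 3`.  Reads are projected through spliced transcript models;
alignments not fully contained in one transcript's exons, antisense to
it, or below the uniqueness proxy (MAPQ ≥ 10 by default) are dropped
with logged counts.

PCR duplicates are collapsed by exact match on (gene, 5′ end, length,
UMI); the 3′ end is implied by the other fields given how the adapter
randomer is attached.  No mismatch tolerance is applied to UMIs — with
6–8 nt randomers and the read depths involved, single-error merging
changes collapse counts marginally while introducing order dependence,
so exact matching was preferred.  Reads with an empty UMI cannot be
deduplicated and are each retained, with a warning.

## Footprint protection geometry

A ribosome protects `full_footprint` nt when elongating (default 28 nt)
of which `downstream_protect` nt (default 10) lie between the A-site
first nucleotide and the mRNA entry tunnel.  For a ribosome whose
A-site sits `d` nt upstream of a truncated 3′ end, the protected length
is

    L(d) = min(full_footprint, max(stalled_range) + d)

which yields 28 for d ≥ 10, the intermediate series 25/22/19 at
d = 7/4/1, and the stalled maximum 18 at d = 0.  The geometry invariant
`full_footprint = max(stalled_range) + downstream_protect` is enforced
at configuration time.  Stalled footprints are emitted with lengths
drawn uniformly from `stalled_range` (15–18 nt): the spread is
attributed to RNase digestion heterogeneity at the 5′ boundary, and no
distribution for it being established, uniform was chosen.  A mammalian
preset (`SimulationConfig.human_preset()`) uses a 31-nt full footprint
with a 13-nt tunnel shield, which shifts the intermediate ladder 3 nt
upstream.

## The simulator

The generator emulates the two candidate mechanisms for stop-codon
footprints on a synthetic transcriptome (single-isoform, single-exon
genes; CDS lengths uniform multiples of 3 in 300–600 nt; 150-nt 3′
UTRs; TAA stop codons; base composition at 42% GC; uniform or
log-normal expression).  Per sampled Ribo-seq read:

* **Background** (uncleaved molecules): elongating 28–30 nt footprints
  uniform over the CDS; with probability `termination_rate` (0.05) a
  21-nt empty-A-site footprint at the stop.  Termination footprints are
  model-independent — their rate does not distinguish the mechanisms.
  An optional `short_background_rate` (default 0) adds short-class
  digestion noise; it is off by default so that a no-cleavage run
  contains no short footprints outside the control locus.
* **model1_Asite**: the cut lands uniformly on the three stop-codon
  positions; a stalled 15–18 nt footprint ends there.  No intermediates
  by construction.
* **model2_runon**: the cut offset is drawn from `cleavage_offset_law`
  (default: probability 0.5 directly on the stop's first nucleotide,
  geometric p = 0.5 tail downstream, truncated at +12).  Cuts
  downstream of the stop expose the end to the exosome, which trims
  5′-ward, halting at each guanosine with probability `g_stall_prob`
  (0.5) and unconditionally at the trailing ribosome's protection edge.
  The trailing ribosome is placed 5–15 codons behind the stop (uniform),
  so trimming can pass upstream of the stop codon — which is what
  produces upstream 3′-end tails on individual genes.  If trimming
  halts at a G while still >2 nt downstream of the stop, the
  terminating ribosome is unaffected and a 21-nt termination read is
  emitted; the G-stalled end is still visible to 3′-RACE.  Otherwise
  the trailing ribosome runs to the truncated end: with probability
  `intermediate_capture_prob` (0.02) a pre-stall snapshot is emitted
  with length 18 + d for d drawn from the codon ladder {1, 4, 7}
  (i.e. 19/22/25 nt, same 3′ end), else the stalled 15–18 nt footprint.
* **Readthrough**: with `readthrough_prob`, the trailing ribosome
  bypasses the stop in frame 0 or −1 and blocks the exosome, stalling
  at the un-trimmed cut.  These are the only short footprints emitted
  downstream of the stop, and they carry codon-quantized 5′ ends
  (modal RNase boundary 15 nt upstream of the A-site, with a 0.05
  one-nt jitter) reflecting translation periodicity — the basis of the
  downstream frame-bias analysis.  Stop-proximal stalls instead carry
  5′ jitter and an exact 3′ end, because there the fragment end, not
  the ribosome, is the fixed boundary.
* **3′-RACE**: fragment 3′ ends mirror molecule 3′ ends (truncation
  events plus intact transcript termini).  End chemistry follows the
  nuclease through `chemistry_map` (SMG-6-like and exosome ends OH,
  the IRE-1-like control site P); the −PNK library drops P ends at
  ligation.  The two libraries are sampled independently.  Gene 1
  carries the IRE-1-like site, 60 nt upstream of its stop, cleaved at
  `ire1_rate` in every model including `none` — the `model="none",
  cleavage_rate=0` configuration emulates a nuclease-dead smg-6
  mutant.
* Cut draws beyond the transcript end are resampled (logged) and
  clamped to the terminus after 100 attempts.

All randomness derives from one integer seed via independent
substreams; a fixed config reproduces byte-identical tables, and
changing only `chemistry_map` changes library membership but no
positions.  The generator does not model library-prep biases
(ligation, circularization), sequencing errors, multi-mapping,
multi-isoform genes or genuine codon-level elongation kinetics, so
passing tests demonstrate the correctness and calibration of the
analysis code under the stated mechanisms — not robustness to every
artifact of real libraries.

## Metagene normalization

Per-gene normalized density is `count(p) / (cds_total / cds_length)`;
a uniformly covered gene reads 1.0 everywhere.  The denominator counts
all supplied reads (every size class) whose anchored end lies in the
CDS — an expression proxy — while the numerator is restricted to the
requested size class.  Genes need `min_reads` (5) CDS reads to enter;
the per-position mean is taken over the genes whose transcript covers
that position, so short 3′ UTRs do not deflate window edges.  The
default window is −50..+50.

## Permutation significance of intermediate footprints

Reads are tallied per gene by (length, 5′-end position relative to the
stop) within a window (default −40..+20, chosen so the stop-proximal
3′ ends of 15–28 nt species land inside); genes need ≥ 5 total reads.
Out-of-window reads count toward the gene total only.  The observed
statistic per (length, position) cell is the mean count over all
retained genes, absences counting zero.

For each of `n_perm` permutations (default 30, as each full-scale
shuffle is expensive; tests use more where stability matters), within
each (gene, length) the observed multiset of counts is reassigned to
distinct positions drawn uniformly from the *entire* window.  This
reading — rather than permuting only among occupied positions — breaks
positional structure while conserving counts and gene sparsity; the
occupied-only variant is available as `mode="occupied"` for sensitivity
analysis.  The z-score uses the permutation sample standard deviation
(n − 1); the p-value is the upper-tail standard-normal probability.
Cells with zero permutation sd and a matching observation get z = 0,
p = 1; a deviating observation with zero sd is flagged in
`undefined_cells` with z = ±∞ and a clamped p.  p-values are floored at
the smallest positive double and not multiple-testing corrected (the
map is read as a significance heat-plot, not a discovery list).  If a
(gene, length) group holds more distinct positions than the window,
injective placement is impossible and the call errors.

## Gene-level analyses

The heatmap uses genes with ≥ 50 short-class 3′ ends in a 100-nt window
fixed as −50..+49 (the anchor nt makes a symmetric window impossible;
the choice is recorded in output metadata) and a single annotated stop
codon across isoforms.  Per-gene CDFs of 3′ ends are ordered by the
half-point — the smallest position where the CDF reaches 0.5 — with
lexicographic tie-breaks.  Raw CDFs are emitted without further row
normalization.

Frame analysis takes reads whose 3′ end is strictly downstream of the
stop codon's last nucleotide and bins their 5′ ends modulo 3 against
the CDS frame; an empty read set returns a flagged-empty result rather
than raising.

3′-end chemistry: per site, `ratio = (count_oh/depth_oh) /
(count_ohp/depth_ohp)` with depths the libraries' total read counts
(counts-per-million–equivalent; the cross-library normalization is a
package choice).  Calls are OH-dominant at ratio ≥ 0.5, P-dominant at
≤ 0.25, otherwise indeterminate, with sites under `min_site_reads`
(10) always indeterminate.  The thresholds are heuristics that separate
the simulated pure-OH (ratio ≈ 1) and pure-P (ratio ≈ 0) regimes with
margin; they are configuration-exposed and not literature values.
Base composition at 3′ ends within 10 nt of the stop is contrasted
against the positional base content of the same region.

## Verification scale

The statistical checks in `tests/test_acceptance.py` run at desk scale:
permutation moments are validated against exhaustive enumeration on a
1-gene/2-entry/6-position instance at 10,000 shuffles; type-I error is
measured on 500 null genes × 120 reads over a 121-position window
(≥ 2000 cells, 150 shuffles); model discrimination uses 300 genes at
2×10⁵ reads with 2% intermediate capture across 10 seeds per model;
the cleavage-rate dose response uses 150 genes at 2×10⁵ reads; heatmap
ordering uses 60 genes with per-gene cut medians spanning −15..+10;
chemistry and frame checks use ~10³ reads per site and ~1.5×10³
downstream reads respectively.

## Known limitations

* The permutation z is normal-approximated; with very sparse counts the
  upper tail is mildly anti-conservative (the type-I check bounds this
  at ≈ 0.05–0.06 under the tested density).
* Multi-isoform quantification is out of scope: one transcript model
  (longest CDS) represents each gene; isoform diversity enters only
  through the multi-stop exclusion flag.
* The simulator's readthrough and trailing-ribosome placement are
  deliberately simple mechanistic stand-ins; rates are free parameters,
  not fitted quantities.
* Phosphate isomers (2′/3′-cyclic vs 3′-P) are treated as one class.
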