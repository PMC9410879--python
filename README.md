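# ribostop

Ribosome footprints and RNA 3′ ends at stop codons: detection of mRNA
decay intermediates from ribosome profiling and 3′-RACE data, with a
mechanistic simulator of the cleavage models that generate them.

## The problem

During nonsense-mediated mRNA decay (NMD), an endonuclease (the SMG-6
PIN domain) cleaves target mRNAs near the termination codon.  The
cleaved, stop-codon-less 5′ fragment strands ribosomes at its new 3′
end, producing short (15–18 nt) ribosome-protected footprints whose 3′
ends sit in the stop codon.  Two mechanisms can explain those
footprints:

1. **Direct A-site cleavage** — the endonuclease cuts inside the
   ribosomal A-site over the stop codon.
2. **Run-on to a trimmed end** — the cut lands at or downstream of the
   stop, the cytoplasmic 3′→5′ exosome trims the fragment back (pausing
   at guanosines), and a trailing ribosome translates up to the
   truncated end and stalls.

The second mechanism makes a distinctive prediction.  A full footprint
is ~28 nt, with ~10 nt of mRNA shielded between the A-site and the mRNA
entry tunnel.  A ribosome still *approaching* a truncated end is
protected out to the fragment end, so its footprint shortens by one
codon per step on the 5′ side while keeping the same 3′ end: an
intermediate series of 25, 22 and 19 nt species

```
L(d) = min(full_footprint, max(stalled_range) + d),   d = A-site → 3′-end distance
     = 28, 25, 22, 19, 18  at  d = 10, 7, 4, 1, 0
```

before collapsing to the stalled 15–18 nt form.  Detecting that rare
series — and telling the two mechanisms apart — is what this package
implements, alongside the supporting analyses: stop-codon-anchored
metagene profiles of normalized read density, per-gene cumulative
distributions of footprint 3′ ends, reading-frame composition of
downstream footprints, and 3′-end chemistry classification from ±PNK
3′-RACE libraries (metal-dependent nucleases leave 3′-OH ends that
ligate without PNK; metal-independent nucleases leave 3′-P ends that do
not).

The intermediate detector follows a permutation scheme: reads are
tallied per gene by (length, 5′-end position relative to the stop),
averaged across genes into an *average footprint density* matrix, and
each (gene, length) count multiset is repeatedly reassigned to random
positions in the window (30 shuffles by default) to obtain a per-cell
z-score and upper-tail normal p-value.

Everything runs on a documented tabular read-ends format (or SAM/BAM +
GFF3), and a built-in simulator generates transcriptomes, Ribo-seq and
±PNK 3′-RACE libraries under either cleavage mechanism — including
exosome G-stalling, readthrough, an smg-6-null mode and a
phosphate-chemistry control locus — so every stage is testable without
external data.

## Worked example

```python
import numpy as np
import ribostop as rs
from ribostop.synthetic_data import SimulationConfig, simulate_transcriptome, simulate_reads

cfg = SimulationConfig(n_genes=100, depth=100_000, seed=7, model="model2_runon")
trome = simulate_transcriptome(cfg)
sim = simulate_reads(trome, cfg)
tx = trome.transcripts()
reads = rs.annotate_relative(rs.collapse_umis(sim.ribo), tx)

tallies = rs.build_tallies(reads, tx, min_reads=5, window=(-40, 20))
dm = rs.permutation_significance(tallies, n_perm=30, seed=7)
for L in (25, 22, 19):
    i = list(dm.lengths).index(L); j = list(dm.positions).index(-(L - 1))
    print(f"length {L:2d} nt, 5' end at {-(L-1):+d}: density {dm.mean_density[i,j]:.2f}, "
          f"z = {dm.z[i,j]:.1f}, p = {dm.p[i,j]:.2e}")

prof = rs.metagene_profile(reads, tx, size_class="short", anchor="3p")
print(f"short-footprint metagene peak: position {prof.positions[np.argmax(prof.density)]}, "
      f"density {prof.density.max():.1f} (n={prof.n_genes} genes)")
```

prints

```
length 25 nt, 5' end at -24: density 1.27, z = 52.2, p = 2.23e-308
length 22 nt, 5' end at -21: density 1.03, z = 60.3, p = 2.23e-308
length 19 nt, 5' end at -18: density 1.00, z = 49.2, p = 2.23e-308
short-footprint metagene peak: position 0, density 69.3 (n=100 genes)
```

The three intermediate lengths share the stop-codon 3′ end (position 0),
so their 5′ ends land at −24/−21/−18 — the codon ladder — and each cell
is overwhelmingly significant against the shuffled background, while the
short-class metagene peaks directly on the first stop-codon nucleotide.
Under `model="model1_Asite"` the same cells show no signal: that
contrast is the discriminating statistic.

The same stages are available as a CLI:

```sh
ribostop simulate --seed 7 --n-genes 100 --depth 100000 --out sim/
ribostop intermediates --reads sim/ribo_reads.tsv --annotation sim/annotation.gff3 --out im/
ribostop heatmap --reads sim/ribo_reads.tsv --annotation sim/annotation.gff3 --out hm/
ribostop endchem --oh-reads sim/race_minus_pnk.tsv --ohp-reads sim/race_plus_pnk.tsv \
    --annotation sim/annotation.gff3 --sequences sim/transcripts.fa --out chem/
```

Every run writes TSV tables with `#` metadata headers plus a
`manifest.json` of resolved parameters and input checksums.

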