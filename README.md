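# tecre

Interval statistics for annotating transposable elements (TEs) as candidate
cis-regulatory elements from chromatin-profiling data.

Histone acetylation marks such as H4K16ac, H3K27ac and H3K122ac are found
not only at gene promoters and enhancers but also at specific TE classes —
the promoter-bearing 5′ UTR of full-length LINE-1 (L1) elements, ERV long
terminal repeats (LTRs) and Alu elements. Deciding whether that co-location
is enrichment rather than chance, and whether marked TEs behave like
regulatory elements (sitting at TAD borders, looping to genes, correlating
with neighbouring gene expression), requires a chain of interval statistics
that is usually assembled ad hoc from bedtools calls and R snippets. `tecre`
packages that chain as a tested, seeded, reusable library with a CLI, for
epigenomics analysts working with peak BEDs, RepeatMasker tables, contact
domains, loop lists and count tables.

## What it computes

- **Consensus ("reproducible") peaks** — replicate peak sets are merged and
  a merged region is kept iff it overlaps peaks from ≥ *k* distinct
  replicates (default *k* = 2).
- **Matched-shuffle enrichment** — for a peak set *P* and an element class
  *E*, the observed count *O* = |{p ∈ P : p overlaps E}| (`intersect -wa -u`
  semantics) is compared with the expectation *E*[O] under a null that
  redraws each peak's start uniformly on its own chromosome, preserving
  chromosome and length. Reported as O/E and log₂(O/E) with an empirical
  95% null interval over R shuffles (default R = 100).
- **(Diff/Sum) TFBS score** — per TF, S = (p_obs − p_exp)/(p_obs + p_exp)
  where p_obs is the TF's percentage of all TFBS records inside
  mark-positive TEs and p_exp the same inside chromosome/length-matched
  random bins. S ∈ [−1, 1].
- **Robust TAD borders** — endpoints of contact domains with corner score
  > 1, kept when the two Hi-C replicates agree within one 10-kb bin
  (greedy nearest matching); plus distance-to-border stratification of TE
  groups with Mann–Whitney U tests.
- **Loop-mediated gene contacts** — a TE contacts a gene when it overlaps
  one loop anchor whose partner anchor overlaps a gene body; group
  fractions are compared with Fisher's exact test.
- **Distance-binned expression** — RPKM = c / ((ℓ/10³)(M/10⁶)); genes are
  binned by gap to the nearest marked TE ([0,10 kb), [10,25 kb),
  [25,50 kb)) and compared with Kruskal–Wallis plus pairwise two-sided
  Dunn tests with Bonferroni correction (exact permutation enumeration at
  tiny n).
- **Synthetic bundle** — a seeded generator
  (`tecre.simulate`) emits a complete, ground-truthed input set (genome,
  TE annotation with full-length L1s, replicate peaks with planted marking
  probabilities, TFBS with planted co-occurrence, replicate domain lists,
  loops, negative-binomial counts with a planted distance-decaying
  fold-effect), so every stage can be exercised and power-checked without
  downloads.

Coordinates are 0-based half-open throughout; rmsk-style and GTF inputs
are converted at the parser boundary. Abutting intervals never count as
overlapping.

## Worked example

```python
from tecre import (SimConfig, simulate, PeakSet, reproducible_peaks,
                   build_element_classes, observed_expected_enrichment)

bundle = simulate(SimConfig(seed=1))
reps = [PeakSet("H4K16ac", r, s) for r, s in bundle.peaks["H4K16ac"].items()]
cp = reproducible_peaks(reps, min_support=2)
classes = build_element_classes(bundle.te_annotation, bundle.genes,
                                chromsizes=bundle.chromsizes)
res = observed_expected_enrichment(cp, classes["L1_5prime"],
                                   bundle.chromsizes, n_shuffles=100, seed=2)
print(f"consensus peaks: {len(cp.intervals)}")
print(f"observed O = {res.observed}, expected E = {res.expected:.2f}")
print(f"O/E = {res.ratio:.2f} (log2 = {res.log2_ratio:.2f})")
```

prints

```
consensus peaks: 424
observed O = 70, expected E = 4.51
O/E = 15.52 (log2 = 3.96)
```

i.e. 424 merged H4K16ac regions survive the two-replicate rule; 70 of them
overlap a full-length-L1 5′ region while matched random placement would hit
about 4.5 — a ~15-fold concentration of the mark at L1 promoters, exactly
the planted structure of the bundle.

The same stages run from the shell:

```sh
te-cre simulate --seed 1 --out sim/
te-cre run --seed 1 --out results_run/
te-cre enrich --peaks results_run/consensus_H4K16ac.bed \
    --elements my_elements.bed --chromsizes sim/genome.chrom.sizes \
    --shuffles 100 --seed 2 --out enrichment.tsv
```

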