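# Methods

This note documents the statistical procedures `tecre` implements, the
modelling assumptions behind the synthetic-data generator, the defaults
that matter, and the numerical edge-case policies. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model

All intervals are 0-based half-open (BED convention) on a named chromosome
with an explicit length table (`ChromSizes`). One-based formats — the
rmsk-style TE table and GTF — are converted once, at the parser boundary,
so no downstream code ever reasons about both conventions. Overlap means
≥ 1 shared bp; abutting intervals (end == start) never overlap anywhere in
the package. `merge_intervals` does union book-ended runs, but that is a
union operation by contract, not an overlap judgement. The gap between two
disjoint intervals is the number of bases strictly between them, so
[100,200) and [250,260) are 50 bp apart. Ties in nearest-neighbour queries
break toward the smaller start coordinate: determinism is worth more here
than any biological argument.

## Consensus peaks

Replicate peak sets for one histone mark are pooled and merged; a merged
region is retained iff it overlaps ≥ 1 bp of peaks from at least
`min_support` (default 2) distinct replicates, and the retained region
keeps the merged coordinates. Union-with-support is the minimal reading of
"merge replicates, keep what reproduces": an intersection rule would
shrink coordinates and discard partially-supported flanks, and nothing in
the procedure being reproduced demands that. `min_support` stays 2
regardless of how many replicates exist. The operation is invariant to
replicate order and idempotent (re-running on its own output with
`min_support=1` returns it unchanged).

## Matched-shuffle enrichment

The null preserves exactly three things about each peak: its existence,
its chromosome, and its length; the start is redrawn uniformly on
`[0, chromlen − length]`. Shuffled peaks may overlap each other and no
exclusion mask (assembly gaps, blacklists) is applied by default — the
randomization matches number, length and chromosome and deliberately
nothing more; an optional exclusion mask would be a different null and is
not the default. Counting is peak-level with `-wa -u` semantics: a peak
counts once however many elements it hits, so O ≤ |peaks| always and
enlarging an element class can never decrease O.

The expected count is the mean over R shuffles (default R = 100). A single
randomization — R = 1 reproduces that literal procedure — makes E a
one-draw estimate with relative noise ~1/√(nφ); averaging R draws costs
only CPU and yields an empirical 95% null interval (2.5th/97.5th
percentiles of the null counts) alongside E. Degenerate cells are emitted
as sentinels, never errors: O>0, E=0 → ratio +∞; O=0, E>0 → ratio 0 with
log₂ = −∞; O=E=0 → NaN (indeterminate). Downstream tables must render the
sentinels explicitly.

## Element classes

- **Full-length L1**: L1-family element with length strictly > 5,000 bp.
  The builder exposes the threshold because annotation versions differ in
  how many elements clear it.
- **L1 5′ region**: strand-aware first W bp of a full-length L1 (default
  W = 900, approximating the human L1 5′ UTR; [start, start+W) on `+`,
  [end−W, end) on `−`, clipped to the element). No canonical bp width for
  "the 5′ UTR" exists in annotation databases, so W is an explicit,
  documented parameter rather than a buried constant.
- **LTR/ERV**: repClass == LTR. **SINE/Alu**: repFamily == Alu.
- **TSS window**: ± w bp (default 500) around the annotated TSS, clipped
  to chromosome bounds. **Gene body**: TSS-to-TES span.

## (Diff/Sum) TFBS score

For one (TE class, mark) cell, TFBS records overlapping the mark-positive
TEs are counted per TF (record-level: one record counts once however many
TEs it touches — the simpler reading of "number of motifs") and the counts
are converted to a percentage distribution across TFs; the expected side
does the same inside chromosome/length-matched random bins. The
normalization axis is across TFs within one cell — each side is a
distribution over TFs summing to 100 — matching the "internal distribution
profile" reading; the alternative (per-TF across classes) is implementable
from the same counts but is not the default. S = (p_obs − p_exp)/(p_obs +
p_exp) is bounded in [−1, 1], antisymmetric under side swap, and defined
as 0 when both sides vanish. The expected side averages counts over
`n_draws` shuffle draws (default 20) before converting to percentages;
`n_draws=1` is the literal single-randomization procedure.

## TAD borders, distances, loops

Contact-domain lists (Arrowhead-style: interval + corner score) from two
Hi-C replicates are reduced to border points — both endpoints of every
domain with score strictly above 1, duplicates collapsed. Borders common
to the two replicates within `max_gap` (default 10,000 bp, one bin at
10-kb resolution) form the robust set. Matching is greedy nearest-first
per chromosome, each point used at most once; no matching rule is dictated
by the procedure being reproduced, and on well-separated borders (spacing
> 2·max_gap, the regime real TAD calls live in) greedy equals the optimal
bipartite matching, which the tests verify against an assignment-solver
oracle. The representative position is the midpoint of the matched pair
floored to the bin grid — which replicate's coordinate "should" be kept is
unknowable, so neither is. The operation is symmetric in replicate order
and idempotent.

Distance-to-border stratification measures the gap from each TE's edges to
the nearest border point (0 if the TE spans it), reports log₁₀(d+1) for
plotting, and compares groups with two-sided Mann–Whitney U: full
enumeration of assignments when both groups have ≤ 8 values (two-sided as
P(|U′ − μ| ≥ |U − μ|), midranks for ties), otherwise the tie-corrected
normal approximation without continuity correction — dropping continuity
keeps the exact asymptotic identity H = z² against the two-group
Kruskal–Wallis test, which the suite checks numerically.

A TE "contacts a gene through a loop" iff it overlaps (≥1 bp) one anchor
of a loop whose other anchor overlaps a gene *body*: the claim being
tested names genes, not promoters, so the gene body is the default and a
TSS window is the caller's option. Group contact fractions are compared
with the conditional two-sided Fisher exact test (scipy's
sum-of-smaller-probabilities rule, verified against a hypergeometric
enumeration oracle to 1e−12); the sample odds ratio ad/bc carries ∞/NaN
sentinels on zero cells.

## RPKM and distance-binned expression

RPKM = c / ((ℓ/10³)(M/10⁶)) with ℓ the exonic length for genes, and is
invariant to jointly scaling counts and library size. Plots and group
comparisons use log₁₀(RPKM + 1); the pseudocount is 1 by choice (none is
dictated). Genes are binned by the gap between the gene body and the
nearest marked TE into left-closed right-open bins, default [0,10 kb),
[10,25 kb), [25,50 kb); an overlapping gene is in the first bin; genes
beyond the last edge are excluded. Gene-body (not TSS) distance is the
default, consistent with the 3D analyses; a TSS option exists. When the
marked and unmarked TE sets must be size-matched, the larger set is
down-sampled uniformly without replacement (seeded).

Groups are compared with Kruskal–Wallis (tie-corrected) followed by
pairwise two-sided Dunn tests — z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ +
1/nⱼ)) with T = Σ(t³−t)/(12(N−1)) — Bonferroni-multiplied by the number of
pairs and capped at 1. When the pooled sample has ≤ 8 values both the H
p-value and the pairwise p-values switch to full permutation enumeration,
because the χ² and normal laws are unreliable there.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs at
desk scale. Default conditions: three 8-Mb chromosomes; ~1,850 TEs across
six subfamilies (L1HS, L1PA7 with 50%/30% full-length fractions forced
> 5 kb; AluY, AluSx at ~300 bp; LTR7, LTR5 at 1.5–1.8 kb), placed
uniformly without overlap per chromosome via the spacings construction
(k sorted uniform points in the free space give the exact uniform law on
non-overlapping configurations; no spatial model is claimed by the data
being emulated, and non-overlap keeps overlap statistics interpretable).

Two marks with three replicates each. A TE is *truly marked* with a
per-subfamily probability (H4K16ac: 0.6/0.4 on L1HS/L1PA7, 0.5/0.3 on
LTR7/LTR5, ≤0.1 on Alus); each replicate then carries a 600-bp peak over
the TE's 5′ region with probability 1 − dropout (dropout 0.1), centered
with N(0, 100 bp) jitter, plus 300 unrelated background peaks per
replicate. The synthetic 5′ region is the strand-aware first 900 bp of the
element (configurable), the same width the element-class builder defaults
to. TFBS: six TFs with 600 background sites each; YY1/CTCF/RAD21
additionally co-occur at truly marked TEs with probability 0.35/0.25/0.25.
TAD replicate B shares 80% of replicate A's borders with ≤ 1 bin of
grid jitter plus mid-domain unique borders; sub-threshold noise domains
carry scores < 1. Loops connect truly marked TEs to a random same-
chromosome gene with probability 0.4 (0.05 for unmarked TEs), 10-kb
anchors.

Expression: each gene draws a lognormal expression rate (median 40
reads/exonic-kb, σ = 0.8 natural-log), multiplied by β (default 1.5) when
the gene body lies within d₀ = 10 kb of a truly marked TE; the
negative-binomial mean is rate × exonic-kb × a lognormal library factor
(σ = 0.1), dispersion 0.1, four samples. Counts scale with exonic length
because that is the sampling model the RPKM normalization inverts; with a
length-free mean, RPKM would anti-correlate with gene length and the
distance bins — which correlate with length through body-edge distance —
would not be exchangeable under β = 1, breaking null calibration for a
reason that has nothing to do with regulation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no sequence (no mappability, GC or repeat-
masking artefacts), no spatial clustering of TEs or genes, no correlation
between marking and 3D structure beyond the planted loops (in particular
TE distance to TAD borders carries no planted signal, so that statistic is
null on synthetic data), no multi-mapping ambiguity, no differential
expression machinery. Every planted fact is recorded in a ground-truth
ledger (which TEs are truly marked, the shared borders, the loop pairs,
the effect genes) so recovery and calibration are scored exactly.

## Pipeline and reproducibility

`run_all` derives one seed per stage from the master seed by hashing the
stage name (SHA-256, reduced below 2³¹), so stages re-run in isolation
reproduce the full run. All outputs are plain-text TSV/BED; the manifest
records every parameter, stage seed and input checksum. Problem sizes in
the test suite and acceptance script (the default bundle, 100-seed
repetition loops, R = 50–100 shuffles, enumeration oracles at n ≤ 8 or
margins ≤ 30) are chosen so the whole suite runs on one CPU in a few
minutes while keeping Monte-Carlo error a small fraction of every asserted
tolerance.

## Known limitations

- The enrichment null does not exclude assembly gaps or blacklists; on
  real genomes that inflates E slightly for classes depleted in gaps.
- Greedy border matching can differ from optimal matching when borders
  crowd within one bin of each other; at 10-kb resolution with real TAD
  spacing this regime does not occur.
- liftOver between assemblies is out of scope; all inputs must share one
  assembly.
- The Dunn z reported alongside exact permutation p-values is the
  asymptotic statistic, kept for effect-size reporting only.
- RPKM is the only normalization offered; TMM/DESeq-style size factors
  and TE-family-aware multi-mapping quantification are out of scope.
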