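"""Seeded generator of a full synthetic input bundle.

The generator emulates the statistical structure of the real inputs — a
multi-chromosome genome; a TE annotation with families and subfamilies
including full-length L1s (forced > 5 kb); replicate CUT&Tag-style peak
sets with planted per-subfamily marking probabilities, replicate dropout
and positional jitter; TFBS clusters with planted co-occurrence at marked
TEs; two replicate contact-domain lists sharing a fraction of borders
within one bin of jitter; loops preferentially connecting marked TEs to
genes; and negative-binomial expression counts with a multiplicative
fold-effect for genes within d0 of a truly marked TE.

It does not simulate sequence: no FASTA, no reads, no signal tracks.
Every emitted interval is bounds-checked, and a ground-truth ledger records
which TEs are truly marked, the shared TAD borders, the planted loop pairs
and the effect genes, so recovery statistics can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .intervals import ChromSizes, IntervalSet
from .te_enrichment import TEAnnotation


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TeFamilySpec:
    """One TE subfamily: how many elements, how long, how often full-length."""

    subfamily: str
    rep_class: str  # LINE / SINE / LTR
    rep_family: str  # L1 / Alu / ERV
    count: int
    length_mean: float  # lognormal median of truncated-element length (bp)
    length_sigma: float = 0.4
    full_length_fraction: float = 0.0  # L1 only: fraction forced > 5 kb
    full_length_mean: float = 6200.0
    full_length_sigma: float = 0.03


@dataclass(frozen=True)
class MarkSpec:
    """One histone mark's replicate peak sets.

    A TE is *truly marked* with probability ``p_mark[subfamily]``; each
    replicate then carries a peak over the TE's 5' region with probability
    ``1 - dropout``, center-jittered by a normal with sd ``jitter_sd``.
    ``background_peaks`` unrelated peaks per replicate model non-TE signal.
    """

    mark: str
    n_replicates: int = 3
    p_mark: dict = field(default_factory=dict)
    background_peaks: int = 300
    dropout: float = 0.1
    jitter_sd: float = 100.0
    peak_width: int = 600


@dataclass(frozen=True)
class TfbsSpec:
    """One TF: background site count plus the probability that each truly
    marked TE (primary mark) carries a co-occurring site in its 5' region."""

    tf: str
    count: int = 600
    p_cooccur: float = 0.02
    site_width: int = 200


@dataclass(frozen=True)
class TadSpec:
    """Replicate contact-domain lists sharing a fraction of borders."""

    borders_per_chrom: int = 25
    shared_fraction: float = 0.8
    jitter_bins: int = 1  # replicate-B jitter, in bins (<= 1 bin = 10 kb)
    bin_size: int = 10_000
    noise_domains_per_chrom: int = 5  # corner score below threshold


@dataclass(frozen=True)
class LoopSpec:
    """Loops preferentially connect truly marked TEs to genes."""

    p_loop: float = 0.4  # truly marked TEs
    p_background: float = 0.05  # unmarked TEs
    anchor_width: int = 10_000


@dataclass(frozen=True)
class ExprSpec:
    """Negative-binomial counts with a planted distance-decaying effect.

    Each gene has a lognormal expression *rate* (reads per kb of exonic
    length; median ``exp(log_mu)``, sd ``sigma_log_mu`` on the natural-log
    scale), and the NB mean is rate x exonic-kb, as the RPKM normalization
    assumes — so RPKM is length-free and distance bins are exchangeable
    when no effect is planted. Genes whose body lies within ``d0`` bp of a
    truly marked TE have their rate multiplied by ``beta``.
    """

    n_genes: int = 2000
    gene_length_mean: float = 4000.0
    gene_length_sigma: float = 0.6
    log_mu: float = float(np.log(40.0))
    sigma_log_mu: float = 0.8
    dispersion: float = 0.1
    beta: float = 1.5
    d0: int = 10_000
    n_samples: int = 4
    lib_size_sigma: float = 0.1


def _default_te_specs() -> tuple[TeFamilySpec, ...]:
    return (
        TeFamilySpec("L1HS", "LINE", "L1", 150, 1500.0, full_length_fraction=0.5),
        TeFamilySpec("L1PA7", "LINE", "L1", 250, 1200.0, full_length_fraction=0.3),
        TeFamilySpec("AluY", "SINE", "Alu", 500, 300.0, length_sigma=0.15),
        TeFamilySpec("AluSx", "SINE", "Alu", 500, 300.0, length_sigma=0.15),
        TeFamilySpec("LTR7", "LTR", "ERV", 250, 1800.0),
        TeFamilySpec("LTR5", "LTR", "ERV", 200, 1500.0),
    )


def _default_mark_specs() -> tuple[MarkSpec, ...]:
    return (
        MarkSpec("H4K16ac", p_mark={"L1HS": 0.6, "L1PA7": 0.4, "LTR7": 0.5,
                                    "LTR5": 0.3, "AluY": 0.1, "AluSx": 0.05}),
        MarkSpec("H3K27ac", p_mark={"L1HS": 0.15, "L1PA7": 0.05, "LTR7": 0.35,
                                    "LTR5": 0.1, "AluY": 0.08, "AluSx": 0.05}),
    )


def _default_tfbs_specs() -> tuple[TfbsSpec, ...]:
    return (
        TfbsSpec("YY1", p_cooccur=0.35),
        TfbsSpec("CTCF", p_cooccur=0.25),
        TfbsSpec("RAD21", p_cooccur=0.25),
        TfbsSpec("SP1"),
        TfbsSpec("NANOG"),
        TfbsSpec("MYC"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full bundle configuration; the defaults are the package's standard
    desk-scale study conditions (three 8-Mb chromosomes, ~1,850 TEs across
    six subfamilies, two marks with three replicates each)."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 8_000_000
    te_specs: tuple[TeFamilySpec, ...] = field(default_factory=_default_te_specs)
    mark_specs: tuple[MarkSpec, ...] = field(default_factory=_default_mark_specs)
    primary_mark: str = "H4K16ac"
    tfbs_specs: tuple[TfbsSpec, ...] = field(default_factory=_default_tfbs_specs)
    tad_spec: TadSpec = field(default_factory=TadSpec)
    loop_spec: LoopSpec = field(default_factory=LoopSpec)
    expr_spec: ExprSpec = field(default_factory=ExprSpec)
    five_prime_width: int = 900

    def __post_init__(self):
        for ms in self.mark_specs:
            for p in ms.p_mark.values():
                if not 0 <= p <= 1:
                    raise ValueError("p_mark must be in [0,1]")
            if not 0 <= ms.dropout <= 1:
                raise ValueError("dropout must be in [0,1]")
        if not 0 <= self.tad_spec.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0,1]")
        if self.expr_spec.beta <= 0:
            raise ValueError("beta must be > 0")


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimTruth:
    """Ground-truth ledger: what was actually planted."""

    te: pd.DataFrame  # te_id, subfamily, + marked_<mark> bool columns
    shared_borders: pd.DataFrame  # chrom, pos_a, pos_b
    loop_pairs: pd.DataFrame  # te_id, gene_id, te_marked
    effect_genes: pd.DataFrame  # gene_id, distance_to_marked_te, has_effect


@dataclass
class SimBundle:
    config: SimConfig
    chromsizes: ChromSizes
    te_annotation: TEAnnotation
    peaks: dict  # mark -> {replicate_name -> IntervalSet}
    tfbs: IntervalSet  # name column = TF
    domains_a: pd.DataFrame
    domains_b: pd.DataFrame
    loops: pd.DataFrame
    genes: pd.DataFrame  # read_gtf_genes layout
    counts: pd.DataFrame
    lengths: pd.Series
    lib_sizes: pd.Series
    truth: SimTruth

    def write(self, outdir) -> dict[str, Path]:
        """Write every component in its standard plain-text format; returns
        the path inventory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _p(key, name):
            paths[key] = outdir / name
            return paths[key]

        self.chromsizes.to_file(_p("chromsizes", "genome.chrom.sizes"))
        tio.write_rmsk(self.te_annotation.df, _p("rmsk", "te_rmsk.tsv"))
        for mark, reps in self.peaks.items():
            for rep, iset in reps.items():
                tio.write_bed(iset, _p(f"peaks_{mark}_{rep}",
                                       f"peaks_{mark}_{rep}.bed"))
        tio.write_bed(self.tfbs, _p("tfbs", "tfbs_clusters.bed"))
        tio.write_domains(self.domains_a, _p("domains_a", "domains_repA.tsv"))
        tio.write_domains(self.domains_b, _p("domains_b", "domains_repB.tsv"))
        tio.write_bedpe(self.loops, _p("loops", "loops.bedpe"))
        write_gtf(self.genes, self._exons, _p("genes", "genes.gtf"))
        tio.write_counts(self.counts, self.lengths, self.lib_sizes,
                         _p("counts", "counts.tsv"))
        self.truth.te.to_csv(_p("truth_te", "truth_te.tsv"), sep="\t", index=False)
        self.truth.shared_borders.to_csv(
            _p("truth_borders", "truth_borders.tsv"), sep="\t", index=False)
        self.truth.loop_pairs.to_csv(
            _p("truth_loops", "truth_loops.tsv"), sep="\t", index=False)
        self.truth.effect_genes.to_csv(
            _p("truth_genes", "truth_genes.tsv"), sep="\t", index=False)
        return paths

    # exon frame is internal plumbing for the GTF writer
    _exons: pd.DataFrame = None

    def marked_te_ids(self, mark: str) -> pd.Series:
        col = f"marked_{mark}"
        return self.truth.te.loc[self.truth.te[col], "te_id"]

    def te_sets_by_truth(self, mark: str) -> tuple[IntervalSet, IntervalSet]:
        """(truly marked, truly unmarked) TE IntervalSets for one mark."""
        flags = self.truth.te[f"marked_{mark}"].to_numpy()
        return (self.te_annotation.to_intervalset(flags),
                self.te_annotation.to_intervalset(~flags))


def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Emit gene/transcript/exon GTF records (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{tattrs}\n")
            sub = exons[exons["gene_id"] == g.gene_id]
            for e in sub.itertuples(index=False):
                fh.write(f"{g.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t"
                         f"{g.strand}\t.\t{tattrs}\n")


# ---------------------------------------------------------------------------
# generation


def _place_nonoverlapping(rng, lengths: np.ndarray, chrom_len: int) -> np.ndarray:
    """Uniformly place non-overlapping intervals of the given lengths.

    Uses the spacings construction: with total free space F, k sorted uniform
    points in [0, F] give the inter-interval gaps, which is the uniform law
    on non-overlapping configurations. Returns starts aligned with
    ``lengths`` (which get a random left-to-right order).
    """
    k = len(lengths)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    free = chrom_len - int(lengths.sum())
    if free < 0:
        raise ValueError(
            f"infeasible packing: {int(lengths.sum())} bp of elements on a "
            f"{chrom_len} bp chromosome")
    order = rng.permutation(k)
    cuts = np.sort(rng.integers(0, free + 1, size=k))
    starts_sorted = cuts + np.concatenate([[0], np.cumsum(lengths[order][:-1])])
    starts = np.empty(k, dtype=np.int64)
    starts[order] = starts_sorted
    return starts


def _five_prime_region(start, end, strand, width):
    if strand == "-":
        return max(end - width, start), end
    return start, min(start + width, end)


def _simulate_tes(rng, config: SimConfig, chroms: list[str]) -> pd.DataFrame:
    rows = []
    for spec in config.te_specs:
        n_full = int(round(spec.count * spec.full_length_fraction))
        lengths = np.empty(spec.count, dtype=np.int64)
        if n_full:
            fl = rng.lognormal(np.log(spec.full_length_mean),
                               spec.full_length_sigma, size=n_full)
            lengths[:n_full] = np.maximum(fl.astype(np.int64), 5001)
        tr = rng.lognormal(np.log(spec.length_mean), spec.length_sigma,
                           size=spec.count - n_full)
        lengths[n_full:] = np.maximum(tr.astype(np.int64), 50)
        chrom_idx = rng.integers(0, len(chroms), size=spec.count)
        strands = np.where(rng.random(spec.count) < 0.5, "+", "-")
        for i in range(spec.count):
            rows.append({
                "te_id": f"{spec.subfamily}_{i}", "name": spec.subfamily,
                "rep_class": spec.rep_class, "rep_family": spec.rep_family,
                "chrom": chroms[chrom_idx[i]], "length": int(lengths[i]),
                "strand": strands[i], "full_length": i < n_full,
            })
    df = pd.DataFrame(rows)
    starts = np.empty(len(df), dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        sel = np.flatnonzero((df["chrom"] == chrom).to_numpy())
        starts[sel] = _place_nonoverlapping(
            rng, df.loc[sel, "length"].to_numpy(), config.chrom_length)
    df["start"] = starts
    df["end"] = starts + df["length"]
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def _simulate_peaks(rng, config: SimConfig, te_df: pd.DataFrame,
                    chromsizes: ChromSizes):
    peaks: dict[str, dict[str, IntervalSet]] = {}
    marked_cols = {}
    chroms = list(chromsizes)
    for ms in config.mark_specs:
        p = te_df["name"].map(ms.p_mark).fillna(0.0).to_numpy()
        truly = rng.random(len(te_df)) < p
        marked_cols[f"marked_{ms.mark}"] = truly
        regions = [_five_prime_region(s, e, st, config.five_prime_width)
                   for s, e, st in zip(te_df["start"], te_df["end"],
                                       te_df["strand"])]
        centers = np.array([(a + b) // 2 for a, b in regions])
        reps = {}
        for r in range(ms.n_replicates):
            rows = []
            emit = truly & (rng.random(len(te_df)) >= ms.dropout)
            jitter = rng.normal(0, ms.jitter_sd, size=len(te_df)).astype(int)
            for i in np.flatnonzero(emit):
                c = int(centers[i] + jitter[i])
                s = max(0, c - ms.peak_width // 2)
                e = min(chromsizes[te_df.at[i, "chrom"]], s + ms.peak_width)
                if e > s:
                    rows.append((te_df.at[i, "chrom"], s, e))
            n_bg = ms.background_peaks
            bg_chrom = rng.integers(0, len(chroms), size=n_bg)
            for ci in bg_chrom:
                chrom = chroms[ci]
                s = int(rng.integers(0, chromsizes[chrom] - ms.peak_width + 1))
                rows.append((chrom, s, s + ms.peak_width))
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            reps[f"rep{r + 1}"] = IntervalSet(df, chromsizes=chromsizes,
                                              provenance=f"{ms.mark}/rep{r + 1}")
        peaks[ms.mark] = reps
    return peaks, marked_cols


def _simulate_tfbs(rng, config: SimConfig, te_df: pd.DataFrame,
                   primary_marked: np.ndarray,
                   chromsizes: ChromSizes) -> IntervalSet:
    chroms = list(chromsizes)
    rows = []
    for spec in config.tfbs_specs:
        for _ in range(spec.count):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = int(rng.integers(0, chromsizes[chrom] - spec.site_width + 1))
            rows.append((chrom, s, s + spec.site_width, spec.tf))
        if spec.p_cooccur > 0:
            hits = primary_marked & (rng.random(len(te_df)) < spec.p_cooccur)
            for i in np.flatnonzero(hits):
                a, b = _five_prime_region(te_df.at[i, "start"],
                                          te_df.at[i, "end"],
                                          te_df.at[i, "strand"],
                                          config.five_prime_width)
                s = int(rng.integers(a, max(a + 1, b - spec.site_width + 1)))
                e = min(s + spec.site_width, chromsizes[te_df.at[i, "chrom"]])
                rows.append((te_df.at[i, "chrom"], s, e, spec.tf))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return IntervalSet(df, chromsizes=chromsizes, provenance="tfbs")


def _simulate_tads(rng, config: SimConfig, chromsizes: ChromSizes):
    ts = config.tad_spec
    bs = ts.bin_size
    rows_a, rows_b, truth_rows = [], [], []
    for chrom, length in chromsizes.items():
        n = ts.borders_per_chrom
        step = length / (n + 1)
        base = (np.arange(1, n + 1) * step
                + rng.uniform(-step / 4, step / 4, size=n))
        pos_a = np.unique((base // bs).astype(np.int64) * bs)
        shared = rng.random(len(pos_a)) < ts.shared_fraction
        jitter = rng.integers(-ts.jitter_bins, ts.jitter_bins + 1,
                              size=len(pos_a)) * bs
        pos_b_shared = pos_a[shared] + jitter[shared]
        # replicate-B-unique borders sit mid-domain, far from any A border
        n_unique = int((~shared).sum())
        uniq_idx = rng.choice(len(pos_a) - 1, size=min(n_unique, len(pos_a) - 1),
                              replace=False) if n_unique else np.array([], int)
        pos_b_unique = ((pos_a[uniq_idx] + pos_a[uniq_idx + 1]) // 2 // bs) * bs
        pos_b = np.unique(np.concatenate([pos_b_shared, pos_b_unique]))
        pos_b = pos_b[(pos_b >= 0) & (pos_b <= length)]
        for pa, pb in zip(pos_a[shared], pos_b_shared):
            truth_rows.append((chrom, int(pa), int(pb)))
        for rows, pos in ((rows_a, pos_a), (rows_b, pos_b)):
            for lo, hi in zip(pos[:-1], pos[1:]):
                rows.append((chrom, int(lo), int(hi),
                             float(rng.uniform(1.2, 3.0))))
            for _ in range(ts.noise_domains_per_chrom):
                s = int(rng.integers(0, length - 20 * bs)) // bs * bs
                rows.append((chrom, s, s + int(rng.integers(5, 20)) * bs,
                             float(rng.uniform(0.1, 0.9))))
    cols = ["chrom", "start", "end", "score"]
    dom_a = pd.DataFrame(rows_a, columns=cols).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    dom_b = pd.DataFrame(rows_b, columns=cols).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos_a", "pos_b"])
    return dom_a, dom_b, truth


def _simulate_genes(rng, config: SimConfig, chromsizes: ChromSizes):
    es = config.expr_spec
    chroms = list(chromsizes)
    rows, exon_rows = [], []
    lengths = np.maximum(rng.lognormal(np.log(es.gene_length_mean),
                                       es.gene_length_sigma,
                                       size=es.n_genes).astype(np.int64), 300)
    chrom_idx = rng.integers(0, len(chroms), size=es.n_genes)
    strands = np.where(rng.random(es.n_genes) < 0.5, "+", "-")
    for i in range(es.n_genes):
        chrom = chroms[chrom_idx[i]]
        glen = int(min(lengths[i], chromsizes[chrom] // 2))
        start = int(rng.integers(0, chromsizes[chrom] - glen + 1))
        end = start + glen
        gid = f"gene_{i}"
        n_ex = int(rng.integers(1, 5))
        if n_ex == 1 or glen < 600:
            blocks = [(start, end)]
        else:
            inner = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2,
                                       replace=False))
            edges = np.concatenate([[0], inner, [glen]])
            blocks = [(start + int(edges[2 * j]), start + int(edges[2 * j + 1]))
                      for j in range(n_ex)]
            blocks = [(a, b) for a, b in blocks if b > a]
        exonic = sum(b - a for a, b in blocks)
        tss = start if strands[i] != "-" else end - 1
        rows.append((gid, chrom, start, end, strands[i], tss, exonic))
        for a, b in blocks:
            exon_rows.append((gid, a, b))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss", "exonic_length"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True)
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "start", "end"])
    return genes, exons


def _simulate_loops(rng, config: SimConfig, te_df: pd.DataFrame,
                    primary_marked: np.ndarray, genes: pd.DataFrame,
                    chromsizes: ChromSizes):
    ls = config.loop_spec
    w = ls.anchor_width
    genes_by_chrom = {c: sub.reset_index(drop=True)
                      for c, sub in genes.groupby("chrom")}
    rows, truth_rows = [], []
    p_vec = np.where(primary_marked, ls.p_loop, ls.p_background)
    hits = rng.random(len(te_df)) < p_vec
    for i in np.flatnonzero(hits):
        chrom = te_df.at[i, "chrom"]
        gsub = genes_by_chrom.get(chrom)
        if gsub is None or not len(gsub):
            continue
        g = gsub.iloc[int(rng.integers(0, len(gsub)))]
        L = chromsizes[chrom]
        tc = int((te_df.at[i, "start"] + te_df.at[i, "end"]) // 2)
        gc = int(g["tss"])
        a1 = (max(0, min(tc - w // 2, L - w)), 0)
        a1 = (a1[0], a1[0] + w)
        a2 = (max(0, min(gc - w // 2, L - w)), 0)
        a2 = (a2[0], a2[0] + w)
        if a1[0] > a2[0]:
            a1, a2 = a2, a1
        rows.append((chrom, a1[0], a1[1], chrom, a2[0], a2[1]))
        truth_rows.append((te_df.at[i, "te_id"], g["gene_id"],
                           bool(primary_marked[i])))
    loops = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                        "start2", "end2"])
    loops = loops.sort_values(["chrom1", "start1", "start2"]).reset_index(
        drop=True)
    truth = pd.DataFrame(truth_rows, columns=["te_id", "gene_id", "te_marked"])
    return loops, truth


def _gene_te_gap(genes: pd.DataFrame, te_df: pd.DataFrame,
                 marked: np.ndarray) -> np.ndarray:
    """Gap (bp) from each gene body to the nearest truly marked TE; inf when
    none share the chromosome."""
    gaps = np.full(len(genes), np.inf)
    marked_by_chrom = {
        c: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for c, sub in te_df[marked].groupby("chrom")}
    for i, (chrom, s, e) in enumerate(zip(genes["chrom"], genes["start"],
                                          genes["end"])):
        hit = marked_by_chrom.get(chrom)
        if hit is None:
            continue
        ts, te_ = hit
        gaps[i] = np.maximum(0, np.maximum(ts - e, s - te_)).min()
    return gaps


def _simulate_counts(rng, config: SimConfig, genes: pd.DataFrame,
                     gaps: np.ndarray):
    es = config.expr_spec
    rate = rng.lognormal(es.log_mu, es.sigma_log_mu, size=len(genes))
    has_effect = gaps < es.d0
    rate = rate * np.where(has_effect, es.beta, 1.0)
    mu = rate * genes["exonic_length"].to_numpy() / 1e3
    lib_factor = rng.lognormal(0.0, es.lib_size_sigma, size=es.n_samples)
    r = 1.0 / es.dispersion
    counts = np.empty((len(genes), es.n_samples), dtype=np.int64)
    for j in range(es.n_samples):
        m = mu * lib_factor[j]
        counts[:, j] = rng.negative_binomial(r, r / (r + m))
    samples = [f"sample_{j + 1}" for j in range(es.n_samples)]
    cdf = pd.DataFrame(counts, index=genes["gene_id"], columns=samples)
    lengths = pd.Series(genes["exonic_length"].to_numpy(),
                        index=genes["gene_id"], name="length")
    lib_sizes = cdf.sum(axis=0)
    truth = pd.DataFrame({"gene_id": genes["gene_id"],
                          "distance_to_marked_te": gaps,
                          "has_effect": has_effect})
    return cdf, lengths, lib_sizes, truth


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate the full bundle; deterministic given ``config.seed``."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chromsizes = ChromSizes({c: config.chrom_length for c in chroms})

    te_df = _simulate_tes(rng, config, chroms)
    peaks, marked_cols = _simulate_peaks(rng, config, te_df, chromsizes)
    primary_marked = marked_cols[f"marked_{config.primary_mark}"]
    tfbs = _simulate_tfbs(rng, config, te_df, primary_marked, chromsizes)
    dom_a, dom_b, border_truth = _simulate_tads(rng, config, chromsizes)
    genes, exons = _simulate_genes(rng, config, chromsizes)
    loops, loop_truth = _simulate_loops(rng, config, te_df, primary_marked,
                                        genes, chromsizes)
    gaps = _gene_te_gap(genes, te_df, primary_marked)
    counts, lengths, lib_sizes, gene_truth = _simulate_counts(
        rng, config, genes, gaps)

    te_truth = te_df[["te_id", "name", "chrom", "start", "end",
                      "full_length"]].copy()
    te_truth = te_truth.rename(columns={"name": "subfamily"})
    for col, vals in marked_cols.items():
        te_truth[col] = vals
    annotation = TEAnnotation(
        te_df[["chrom", "start", "end", "strand", "name", "rep_class",
               "rep_family"]].copy(), chromsizes=chromsizes)
    bundle = SimBundle(
        config=config, chromsizes=chromsizes, te_annotation=annotation,
        peaks=peaks, tfbs=tfbs, domains_a=dom_a, domains_b=dom_b, loops=loops,
        genes=genes, counts=counts, lengths=lengths, lib_sizes=lib_sizes,
        truth=SimTruth(te=te_truth, shared_borders=border_truth,
                       loop_pairs=loop_truth, effect_genes=gene_truth))
    bundle._exons = exons
    return bundle
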