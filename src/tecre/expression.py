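"""RPKM and distance-binned expression comparison near marked vs unmarked TEs.

RPKM = c / ((l/1e3) * (M/1e6)) for count c, feature length l (exonic length
for genes) and library size M. Genes are stratified by the gap between the
gene body and the nearest TE of a set (e.g. H4K16ac-positive full-length
L1s) into left-closed right-open bins ([0,10 kb), [10,25 kb), [25,50 kb) by
default; genes beyond the last edge are excluded. Bins are compared with a
Kruskal-Wallis test followed by pairwise two-sided Dunn tests with
Bonferroni correction; tiny samples fall back to exact permutation
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, closest_distance, sample_intervals


@dataclass
class ExpressionTable:
    """Feature counts with lengths and library sizes.

    counts: features x samples integer frame; lengths: bp per feature
    (exonic length for genes, element length for TEs); lib_sizes: total
    mapped reads per sample.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self):
        self.lengths = self.lengths.reindex(self.counts.index)
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every feature needs a positive length")
        if self.lib_sizes.isna().any() or (self.lib_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


def rpkm(table: ExpressionTable) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads, per sample."""
    kb = table.lengths.to_numpy()[:, None] / 1e3
    millions = table.lib_sizes.to_numpy()[None, :] / 1e6
    return pd.DataFrame(table.counts.to_numpy() / (kb * millions),
                        index=table.counts.index, columns=table.counts.columns)


def log10_rpkm(table: ExpressionTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(RPKM + pseudocount), the plotted scale."""
    return np.log10(rpkm(table) + pseudocount)


@dataclass
class DistanceBinSpec:
    """Left-closed right-open distance bins; genes beyond the last edge are
    excluded from the comparison."""

    edges: tuple[int, ...] = (0, 10_000, 25_000, 50_000)

    def __post_init__(self):
        if list(self.edges) != sorted(set(self.edges)):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            out.append(f"[{lo},{hi})")
        return out


def assign_distance_bins(genes: IntervalSet, tes: IntervalSet,
                         spec: DistanceBinSpec | None = None) -> pd.Series:
    """Bin label per gene by gap to the nearest TE (0 on overlap -> first bin).

    Indexed by gene name in the genes set's canonical order; genes beyond the
    last edge (or on chromosomes with no TE) get ``None``.
    """
    spec = spec or DistanceBinSpec()
    if len(tes) == 0:
        raise ValueError("empty TE set")
    near = closest_distance(genes, tes)
    labels = np.array(spec.labels + [None], dtype=object)
    d = near["distance"].to_numpy()
    idx = np.searchsorted(spec.edges[1:], d, side="right")  # [lo,hi) bins
    idx = np.where(np.isnan(d), len(spec.labels), idx).astype(int)
    return pd.Series(labels[idx], index=near["name"].to_numpy(), name="bin")


def balanced_te_sets(marked: IntervalSet, unmarked: IntervalSet,
                     seed: int = 0) -> tuple[IntervalSet, IntervalSet]:
    """Down-sample the larger of two TE sets to the smaller's cardinality
    (seeded, without replacement), so group comparisons use equal n."""
    if len(marked) == 0 or len(unmarked) == 0:
        raise ValueError("both TE sets must be non-empty")
    n = min(len(marked), len(unmarked))
    if len(marked) > n:
        marked = sample_intervals(marked, n, seed=seed)
    elif len(unmarked) > n:
        unmarked = sample_intervals(unmarked, n, seed=seed)
    return marked, unmarked


@dataclass
class RankTestResult:
    """Kruskal-Wallis H/p plus pairwise Dunn z and Bonferroni-adjusted p."""

    h: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    exact: bool = False


def _dunn_asymptotic(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    groups = sorted(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    rank_means, sizes, start = {}, {}, 0
    for g in groups:
        n = len(values_by_group[g])
        rank_means[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = comb(len(groups), 2)
    rows = []
    for a, b in combinations(groups, 2):
        se = sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (rank_means[a] - rank_means[b]) / se
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw,
                     "p_adj": min(1.0, p_raw * n_pairs)})
    return pd.DataFrame(rows)


def _kw_h(ranks: np.ndarray, sizes: list[int], tie_corr: float) -> float:
    n_total = len(ranks)
    h, start = 0.0, 0
    for n in sizes:
        h += ranks[start:start + n].sum() ** 2 / n
        start += n
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    return h / tie_corr if tie_corr > 0 else 0.0


def _assignments(n_total: int, sizes: list[int]):
    """Yield index tuples per group for every distinct assignment of
    n_total items into groups of the given sizes."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for chosen in combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(chosen))
            for tail in rec(rest, sizes_left[1:]):
                yield [chosen] + tail
    yield from rec(tuple(range(n_total)), sizes)


def _exact_rank_test(values_by_group: dict[str, np.ndarray]) -> RankTestResult:
    """Full permutation enumeration of the Kruskal-Wallis H and the pairwise
    rank-mean differences, for tiny samples where the chi-square law is
    unreliable."""
    groups = sorted(values_by_group)
    sizes = [len(values_by_group[g]) for g in groups]
    pooled = np.concatenate([values_by_group[g] for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float((tie_counts ** 3 - tie_counts).sum()) / (
        n_total ** 3 - n_total)
    h_obs = _kw_h(ranks, sizes, tie_corr)
    pair_idx = list(combinations(range(len(groups)), 2))
    obs_dev = {}
    start_of = np.cumsum([0] + sizes)
    means_obs = [ranks[start_of[i]:start_of[i + 1]].mean()
                 for i in range(len(groups))]
    for i, j in pair_idx:
        obs_dev[(i, j)] = abs(means_obs[i] - means_obs[j])
    h_hits = 0
    pair_hits = {k: 0 for k in pair_idx}
    total = 0
    for assignment in _assignments(n_total, sizes):
        total += 1
        means = [ranks[list(grp)].mean() for grp in assignment]
        flat = np.concatenate([ranks[list(grp)] for grp in assignment])
        h = _kw_h(flat, sizes, tie_corr)
        if h >= h_obs - 1e-9:
            h_hits += 1
        for i, j in pair_idx:
            if abs(means[i] - means[j]) >= obs_dev[(i, j)] - 1e-9:
                pair_hits[(i, j)] += 1
    n_pairs = len(pair_idx)
    rows = []
    asym = _dunn_asymptotic(values_by_group)  # keep z for reporting
    for (i, j), row in zip(pair_idx, asym.itertuples(index=False)):
        p_raw = pair_hits[(i, j)] / total
        rows.append({"group_a": groups[i], "group_b": groups[j], "z": row.z,
                     "p_raw": p_raw, "p_adj": min(1.0, p_raw * n_pairs)})
    return RankTestResult(h=h_obs, p=h_hits / total,
                          pairwise=pd.DataFrame(rows), exact=True)


def group_rank_test(values_by_group: dict[str, np.ndarray],
                    exact_max_n: int = 8) -> RankTestResult:
    """Kruskal-Wallis across groups plus pairwise Dunn post hoc tests with
    Bonferroni correction.

    When the pooled sample is at most ``exact_max_n`` values, both the H
    p-value and the pairwise p-values come from full permutation enumeration
    instead of the asymptotic laws.
    """
    if len(values_by_group) < 2:
        raise ValueError("need >=2 groups")
    clean = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in clean.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    n_total = sum(len(v) for v in clean.values())
    if n_total <= exact_max_n:
        return _exact_rank_test(clean)
    groups = sorted(clean)
    pooled = [clean[g] for g in groups]
    if all((v == pooled[0][0]).all() for v in pooled):
        # identical constant groups: H undefined in scipy; by exchangeability
        # there is nothing to test
        pairwise = _dunn_asymptotic(clean)
        return RankTestResult(h=0.0, p=1.0, pairwise=pairwise)
    h, p = stats.kruskal(*pooled)
    return RankTestResult(h=float(h), p=float(p),
                          pairwise=_dunn_asymptotic(clean))
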