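"""Replicate-consensus peak derivation and peak-set summaries.

A "reproducible" (consensus) peak is a merged-union region supported by
peaks from at least ``min_support`` distinct replicates — the filter the
profiling analyses apply before any enrichment statistic. The union-with-
support reading keeps merged coordinates rather than intersections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, intersect_any, merge_intervals, overlap_mask


@dataclass
class PeakSet:
    """One replicate's peak calls for one histone mark."""

    mark: str
    replicate: str
    intervals: IntervalSet

    def __post_init__(self):
        if len(self.intervals) == 0:
            raise ValueError(f"empty peak set {self.mark}/{self.replicate}")


@dataclass
class ConsensusPeaks:
    """Merged regions supported by >= min_support distinct replicates."""

    mark: str
    intervals: IntervalSet
    min_support: int


def reproducible_peaks(replicates: list[PeakSet], min_support: int = 2) -> ConsensusPeaks:
    """Merge all replicate peaks; keep merged regions overlapping >=1 bp of
    peaks from at least ``min_support`` distinct replicates."""
    if not replicates:
        raise ValueError("no replicate peak sets")
    marks = {r.mark for r in replicates}
    if len(marks) != 1:
        raise ValueError(f"mixed marks in one consensus call: {sorted(marks)}")
    if len(replicates) < min_support:
        raise ValueError(
            f"{len(replicates)} replicate(s) < min_support={min_support}")
    union = IntervalSet(
        pd.concat([r.intervals.df for r in replicates], ignore_index=True),
        chromsizes=replicates[0].intervals.chromsizes)
    merged = merge_intervals(union)
    support = np.zeros(len(merged), dtype=int)
    for rep in replicates:
        support += overlap_mask(merged, rep.intervals).astype(int)
    kept = merged.subset(support >= min_support)
    return ConsensusPeaks(mark=marks.pop(), intervals=kept,
                          min_support=min_support)


@dataclass
class OverlapSummary:
    """Exact-subset region counts (upset-style) plus pairwise Jaccard."""

    subset_counts: dict[frozenset, int]
    jaccard: pd.DataFrame

    def count(self, *marks: str) -> int:
        return self.subset_counts.get(frozenset(marks), 0)


def overlap_summary(sets: dict[str, ConsensusPeaks] | dict[str, IntervalSet]) -> OverlapSummary:
    """Partition the union of all peak sets into merged regions and count, for
    every non-empty mark subset, the regions supported by exactly that subset.
    Region units are merged-union regions, not input peaks."""
    if len(sets) < 2:
        raise ValueError("overlap_summary needs >=2 peak sets")
    isets = {m: (v.intervals if isinstance(v, ConsensusPeaks) else v)
             for m, v in sets.items()}
    union = IntervalSet(
        pd.concat([s.df for s in isets.values()], ignore_index=True),
        chromsizes=next(iter(isets.values())).chromsizes)
    regions = merge_intervals(union)
    membership = {m: overlap_mask(regions, s) for m, s in isets.items()}
    marks = list(isets)
    counts: dict[frozenset, int] = {}
    stack = np.column_stack([membership[m] for m in marks])
    for row in stack:
        key = frozenset(m for m, hit in zip(marks, row) if hit)
        if key:
            counts[key] = counts.get(key, 0) + 1
    jac = pd.DataFrame(np.eye(len(marks)), index=marks, columns=marks)
    for m1, m2 in combinations(marks, 2):
        both = int((membership[m1] & membership[m2]).sum())
        either = int((membership[m1] | membership[m2]).sum())
        j = both / either if either else np.nan
        jac.loc[m1, m2] = jac.loc[m2, m1] = j
    return OverlapSummary(subset_counts=counts, jaccard=jac)


@dataclass
class FeatureAssignment:
    """Single-label feature assignment of peaks with percentage distribution."""

    assignments: pd.DataFrame  # chrom, start, end, feature
    percentages: pd.Series  # feature label -> percent of peaks; sums to 100

    def __post_init__(self):
        total = float(self.percentages.sum())
        if len(self.percentages) and not np.isclose(total, 100.0):
            raise ValueError(f"percentages sum to {total}, not 100")


UNASSIGNED = "unassigned"


def assign_by_feature(peaks: ConsensusPeaks | IntervalSet,
                      features: IntervalSet) -> FeatureAssignment:
    """Assign each peak to the feature label with the largest bp overlap.

    Ties break toward the feature with the earliest start; peaks hitting no
    feature go to an explicit "unassigned" class. Feature labels are the
    ``name`` column of ``features``.
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    pk = peaks.intervals if isinstance(peaks, ConsensusPeaks) else peaks
    f_by_chrom = {c: sub for c, sub in features.df.groupby("chrom", sort=False)}
    labels = []
    for row in pk.df.itertuples(index=False):
        sub = f_by_chrom.get(row.chrom)
        if sub is None:
            labels.append(UNASSIGNED)
            continue
        fs = sub["start"].to_numpy()
        fe = sub["end"].to_numpy()
        ov = np.minimum(fe, row.end) - np.maximum(fs, row.start)
        best_ov = ov.max(initial=0)
        if best_ov <= 0:
            labels.append(UNASSIGNED)
            continue
        cand = np.flatnonzero(ov == best_ov)
        j = cand[np.argmin(fs[cand])]  # earliest feature start wins ties
        labels.append(sub["name"].to_numpy()[j])
    assignments = pk.df[["chrom", "start", "end"]].copy()
    assignments["feature"] = labels
    pct = assignments["feature"].value_counts() / len(assignments) * 100.0
    return FeatureAssignment(assignments=assignments, percentages=pct)


@dataclass
class GroupedCorrelation:
    """Per-group signal means and the Pearson correlation across them."""

    group_means: pd.DataFrame  # index: group; columns: signal_a, signal_b
    r: float
    p: float


def grouped_signal_correlation(signal_a: pd.Series, signal_b: pd.Series,
                               grouping: pd.Series) -> GroupedCorrelation:
    """Correlate two per-element signals at the subfamily level.

    Element-level signals are averaged within each grouping level (e.g. L1
    subfamily); Pearson r with two-sided p is computed across group means.
    With a zero-variance side, r and p are returned as NaN rather than
    raising — the caller decides how to render an undefined correlation.
    """
    shared = signal_a.index.intersection(signal_b.index).intersection(
        grouping.index)
    if len(shared) == 0:
        raise ValueError("no shared element ids")
    g = grouping.loc[shared]
    means = pd.DataFrame({
        "signal_a": signal_a.loc[shared].groupby(g).mean(),
        "signal_b": signal_b.loc[shared].groupby(g).mean(),
    })
    if len(means) < 3:
        raise ValueError(f"need >=3 groups, got {len(means)}")
    if means["signal_a"].nunique() == 1 or means["signal_b"].nunique() == 1:
        return GroupedCorrelation(group_means=means, r=float("nan"),
                                  p=float("nan"))
    r, p = stats.pearsonr(means["signal_a"], means["signal_b"])
    return GroupedCorrelation(group_means=means, r=float(r), p=float(p))
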