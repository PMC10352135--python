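"""TAD-border consensus, border-distance stratification, and loop-mediated
TE-gene contact statistics.

Contact-domain lists (Arrowhead-style, one per Hi-C replicate) are reduced
to border points; borders with corner score above a threshold that agree
between the two replicates within one bin (<=10 kb gap by default) form the
robust border set. TE groups are then compared on distance-to-border
(Mann-Whitney U) and on the fraction of TEs contacting a gene through a
chromatin loop (Fisher's exact test).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ChromSizes, IntervalSet, overlap_mask


# ---------------------------------------------------------------------------
# borders


def domain_borders(domains: pd.DataFrame, score_threshold: float = 1.0) -> pd.DataFrame:
    """Border points of contact domains with corner score strictly above the
    threshold ("a score above one"); both endpoints count, duplicates collapse.

    Returns a frame with columns chrom, pos, sorted, unique."""
    sel = domains[domains["score"] > score_threshold]
    pts = pd.concat([
        sel[["chrom", "start"]].rename(columns={"start": "pos"}),
        sel[["chrom", "end"]].rename(columns={"end": "pos"}),
    ])
    pts = pts.drop_duplicates().sort_values(["chrom", "pos"])
    return pts.reset_index(drop=True)


@dataclass(frozen=True)
class TadBorder:
    """A replicate-supported border: representative position plus the matched
    per-replicate member positions."""

    chrom: str
    position: int
    members: tuple[int, ...]  # (pos in rep A, pos in rep B)
    replicates: tuple[str, ...] = ("A", "B")


def robust_borders(rep_a: pd.DataFrame, rep_b: pd.DataFrame,
                   max_gap: int = 10_000, bin_size: int = 10_000) -> list[TadBorder]:
    """Common borders between two replicates within ``max_gap`` (one 10-kb bin).

    Matching is greedy nearest-first per chromosome, each point used at most
    once; on well-separated borders this equals the optimal bipartite
    matching. The representative position is the midpoint of the matched
    pair floored to the bin grid. Symmetric in replicate order.
    """
    out: list[TadBorder] = []
    a_by = {c: sub["pos"].to_numpy() for c, sub in rep_a.groupby("chrom")}
    b_by = {c: sub["pos"].to_numpy() for c, sub in rep_b.groupby("chrom")}
    for chrom in sorted(set(a_by) & set(b_by)):
        pa, pb = a_by[chrom], b_by[chrom]
        pairs = []
        for i, x in enumerate(pa):
            for j, y in enumerate(pb):
                gap = abs(int(x) - int(y))
                if gap <= max_gap:
                    pairs.append((gap, int(x), int(y), i, j))
        pairs.sort()  # nearest first; ties by (a pos, b pos) for determinism
        used_a: set[int] = set()
        used_b: set[int] = set()
        for gap, x, y, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            mid = (x + y) // 2
            pos = (mid // bin_size) * bin_size
            out.append(TadBorder(chrom=chrom, position=pos, members=(x, y)))
    out.sort(key=lambda b: (b.chrom, b.position, b.members))
    return out


def borders_to_frame(borders: list[TadBorder]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.position, b.members[0], b.members[1]) for b in borders],
        columns=["chrom", "pos", "member_a", "member_b"])


# ---------------------------------------------------------------------------
# rank test on distances


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments: p = Pr(|U' - n1*n2/2| >= |U_obs - n1*n2/2|). Handles ties
    through midranks."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = comb(n1 + n2, n1)
    idx = range(n1 + n2)
    for group1 in combinations(idx, n1):
        u = ranks[list(group1)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev_obs - 1e-9:
            hits += 1
    return float(u_obs), hits / total


def mannwhitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration when both groups are at
    most ``exact_max_n``, else the tie-corrected normal approximation
    (no continuity correction, so that H == z**2 holds against
    Kruskal-Wallis on two groups). Returns (U of the first sample, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in Mann-Whitney test")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_mwu_p(x, y)
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                              use_continuity=False, method="asymptotic")
    return float(u), float(p)


@dataclass
class DistanceResult:
    """Distance-to-border samples per TE group plus pairwise Mann-Whitney p."""

    distances: dict[str, np.ndarray]
    log10_distances: dict[str, np.ndarray]  # log10(d + 1), the plotted scale
    pairwise: pd.DataFrame  # group_a, group_b, u, p


def distance_to_borders(groups: dict[str, IntervalSet],
                        borders: list[TadBorder] | pd.DataFrame,
                        exact_max_n: int = 8) -> DistanceResult:
    """Distance from each TE to the nearest robust border point, per group,
    with pairwise two-sided Mann-Whitney U tests between groups.

    A TE spanning a border point is at distance 0; TEs on chromosomes with
    no border are excluded from that group's sample.
    """
    if isinstance(borders, list):
        bdf = borders_to_frame(borders)
    else:
        bdf = borders
    if len(bdf) == 0:
        raise ValueError("no borders")
    if len(groups) < 2:
        raise ValueError("need >=2 TE groups")
    b_by = {c: np.sort(sub["pos"].to_numpy()) for c, sub in bdf.groupby("chrom")}
    dists: dict[str, np.ndarray] = {}
    for label, iset in groups.items():
        if len(iset) == 0:
            raise ValueError(f"empty TE group {label!r}")
        vals = []
        for row in iset.df.itertuples(index=False):
            pos = b_by.get(row.chrom)
            if pos is None:
                continue
            # border point p: distance 0 if start <= p < end, else bp strictly
            # between the TE edge and the point
            d = np.maximum(0, np.maximum(pos - (row.end - 1), row.start - pos))
            vals.append(int(d.min()))
        dists[label] = np.asarray(vals, dtype=float)
    rows = []
    for a, b in combinations(sorted(dists), 2):
        u, p = mannwhitney_u(dists[a], dists[b], exact_max_n=exact_max_n)
        rows.append({"group_a": a, "group_b": b, "u": u, "p": p})
    return DistanceResult(
        distances=dists,
        log10_distances={k: np.log10(v + 1) for k, v in dists.items()},
        pairwise=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# loops


def fisher_exact(table) -> tuple[float, float]:
    """Conditional two-sided Fisher's exact test on a 2x2 count table.

    Returns (sample odds ratio, p); the odds ratio is ad/bc with an infinity
    sentinel on a zero denominator cell and NaN when indeterminate (0/0).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a non-negative 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


@dataclass
class ContactTable:
    """2x2 contact/no-contact counts for a pair of TE groups."""

    group_a: str
    group_b: str
    table: np.ndarray  # [[a_contact, a_no], [b_contact, b_no]]
    odds_ratio: float
    p: float


@dataclass
class ContactResult:
    fractions: pd.Series  # group -> fraction of TEs contacting a gene
    counts: pd.Series  # group -> number contacting
    sizes: pd.Series  # group -> group size
    tables: list[ContactTable]


def loop_gene_contacts(tes: dict[str, IntervalSet], loops: pd.DataFrame,
                       genes: IntervalSet,
                       chromsizes: ChromSizes | None = None) -> ContactResult:
    """Fraction of TEs per group that contact a gene through a chromatin loop.

    A TE contacts a gene iff it overlaps (>=1 bp) one anchor of a loop whose
    other anchor overlaps a gene body (>=1 bp). Every group pair gets a 2x2
    Fisher's exact test on contacting/non-contacting counts.
    """
    if len(loops):
        a1 = IntervalSet(loops.rename(columns={
            "chrom1": "chrom", "start1": "start", "end1": "end"})[
            ["chrom", "start", "end"]], chromsizes=chromsizes)
        a2 = IntervalSet(loops.rename(columns={
            "chrom2": "chrom", "start2": "start", "end2": "end"})[
            ["chrom", "start", "end"]], chromsizes=chromsizes)
        # anchors whose partner anchor hits a gene body; careful: IntervalSet
        # canonicalizes order, so compute gene hits on the raw frames
        g1 = _hits_raw(loops, "1", genes)
        g2 = _hits_raw(loops, "2", genes)
        qual = []
        sub = loops[g2]
        qual.append(sub.rename(columns={"chrom1": "chrom", "start1": "start",
                                        "end1": "end"})[["chrom", "start", "end"]])
        sub = loops[g1]
        qual.append(sub.rename(columns={"chrom2": "chrom", "start2": "start",
                                        "end2": "end"})[["chrom", "start", "end"]])
        qual_df = pd.concat(qual, ignore_index=True)
    else:
        qual_df = pd.DataFrame(columns=["chrom", "start", "end"])
    fractions, counts, sizes = {}, {}, {}
    contact_masks = {}
    for label, iset in tes.items():
        if len(qual_df):
            anchors = IntervalSet(qual_df, chromsizes=chromsizes)
            mask = overlap_mask(iset, anchors)
        else:
            mask = np.zeros(len(iset), dtype=bool)
        contact_masks[label] = mask
        sizes[label] = len(iset)
        counts[label] = int(mask.sum())
        fractions[label] = counts[label] / sizes[label] if sizes[label] else np.nan
    tables = []
    for a, b in combinations(sorted(tes), 2):
        t = np.array([[counts[a], sizes[a] - counts[a]],
                      [counts[b], sizes[b] - counts[b]]])
        odds, p = fisher_exact(t)
        tables.append(ContactTable(group_a=a, group_b=b, table=t,
                                   odds_ratio=odds, p=p))
    return ContactResult(fractions=pd.Series(fractions), counts=pd.Series(counts),
                         sizes=pd.Series(sizes), tables=tables)


def _hits_raw(loops: pd.DataFrame, which: str, genes: IntervalSet) -> np.ndarray:
    """Per-loop bool: anchor `which` overlaps >=1 gene body (row order kept)."""
    hit = np.zeros(len(loops), dtype=bool)
    g_by = {c: sub for c, sub in genes.df.groupby("chrom", sort=False)}
    chrom_col, s_col, e_col = f"chrom{which}", f"start{which}", f"end{which}"
    for i, (chrom, s, e) in enumerate(zip(loops[chrom_col], loops[s_col],
                                          loops[e_col])):
        sub = g_by.get(chrom)
        if sub is None:
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        hit[i] = bool(((gs < e) & (ge > s)).any())
    return hit
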