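"""TAD-border consensus, border-distance tests, loop contacts, and the exact
small-sample statistics, each against independent enumeration oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from tecre.chromatin3d import (borders_to_frame, distance_to_borders,
                               domain_borders, fisher_exact,
                               loop_gene_contacts, mannwhitney_u,
                               robust_borders)
from tecre.intervals import ChromSizes, IntervalSet

from conftest import random_intervalset


# ---------------------------------------------------------------------------
# domain borders


def test_domain_endpoints_become_borders():
    doms = pd.DataFrame({"chrom": ["chr1"], "start": [100_000],
                         "end": [300_000], "score": [2.0]})
    pts = domain_borders(doms)
    assert pts["pos"].tolist() == [100_000, 300_000]


def test_low_score_domains_filtered():
    doms = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000],
                         "score": [0.5]})
    assert len(domain_borders(doms)) == 0


def test_borders_match_bruteforce_endpoint_extraction():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(5, 40))
        doms = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=n),
            "start": rng.integers(0, 10**6, size=n),
            "score": rng.uniform(0, 3, size=n)})
        doms["end"] = doms["start"] + rng.integers(10**4, 10**5, size=n)
        pts = domain_borders(doms, score_threshold=1.0)
        expected = set()
        for r in doms.itertuples(index=False):
            if r.score > 1.0:
                expected.add((r.chrom, r.start))
                expected.add((r.chrom, r.end))
        assert set(zip(pts["chrom"], pts["pos"])) == expected


# ---------------------------------------------------------------------------
# robust borders


def _pts(chrom_pos):
    return pd.DataFrame(chrom_pos, columns=["chrom", "pos"])


def test_identical_border_lists_fully_retained():
    pts = _pts([("chr1", 100_000), ("chr1", 400_000), ("chr2", 50_000)])
    borders = robust_borders(pts, pts)
    assert [(b.chrom, b.position) for b in borders] == \
        [("chr1", 100_000), ("chr1", 400_000), ("chr2", 50_000)]
    assert all(b.members[0] == b.members[1] for b in borders)


def test_gap_beyond_one_bin_not_matched():
    a = _pts([("chr1", 100_000)])
    b = _pts([("chr1", 125_000)])
    assert robust_borders(a, b, max_gap=10_000) == []


def test_robust_borders_symmetric_and_bounded():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = _pts([("chr1", int(p)) for p in
                  np.sort(rng.integers(0, 10**6, size=15))])
        b = _pts([("chr1", int(p)) for p in
                  np.sort(rng.integers(0, 10**6, size=12))])
        fwd = robust_borders(a, b)
        rev = robust_borders(b, a)
        assert [(x.chrom, x.position) for x in fwd] == \
            [(x.chrom, x.position) for x in rev]
        assert len(fwd) <= min(len(a), len(b))


def test_robust_borders_idempotent():
    rng = np.random.default_rng(2)
    a = _pts([("chr1", int(p)) for p in np.sort(rng.integers(0, 10**6, 20))])
    b = _pts([("chr1", int(p + rng.integers(-9000, 9000)))
              for p in a["pos"]])
    once = borders_to_frame(robust_borders(a, b))
    pts = once[["chrom", "pos"]]
    twice = borders_to_frame(robust_borders(pts, pts))
    assert twice["pos"].tolist() == sorted(pts["pos"].tolist())


def test_greedy_matching_count_equals_optimal_on_small_instances():
    """On instances of <=50 borders with jitter <= max_gap, greedy
    nearest-first matching finds as many pairs as the optimal assignment
    (scipy linear_sum_assignment as the exhaustive matching oracle)."""
    rng = np.random.default_rng(3)
    max_gap = 10_000
    for _ in range(30):
        # replicate-jitter fixture: well-separated A borders; B carries a
        # shared subset jittered within one bin plus unmatchable extras
        na = int(rng.integers(5, 50))
        pa = np.cumsum(rng.integers(4 * max_gap, 10 * max_gap, size=na))
        shared = rng.random(na) < 0.7
        pb_shared = pa[shared] + rng.integers(-max_gap, max_gap + 1,
                                              size=int(shared.sum()))
        pb_extra = pa[~shared] + 2 * max_gap + 1
        pb = np.sort(np.concatenate([pb_shared, pb_extra]))
        got = len(robust_borders(_pts([("chr1", int(p)) for p in pa]),
                                 _pts([("chr1", int(p)) for p in pb]),
                                 max_gap=max_gap))
        # oracle: maximize number of matched pairs within max_gap
        nb = len(pb)
        cost = np.full((na, nb), 1.0)
        for i in range(na):
            for j in range(nb):
                if abs(int(pa[i]) - int(pb[j])) <= max_gap:
                    cost[i, j] = 0.0
        ri, cj = linear_sum_assignment(cost)
        optimal = int((cost[ri, cj] == 0).sum())
        assert got == optimal


def test_recovers_planted_shared_borders(bundle):
    pts_a = domain_borders(bundle.domains_a)
    pts_b = domain_borders(bundle.domains_b)
    borders = robust_borders(pts_a, pts_b)
    truth = bundle.truth.shared_borders
    got = {(b.chrom, b.position) for b in borders}
    recalled = sum(
        any(c == chrom and abs(p - pa) <= 10_000 for c, p in got)
        for chrom, pa in zip(truth["chrom"], truth["pos_a"]))
    assert recalled / len(truth) >= 0.95


# ---------------------------------------------------------------------------
# distances + Mann-Whitney


def test_te_spanning_border_distance_zero():
    cs = ChromSizes({"chr1": 10**6})
    groups = {
        "span": IntervalSet.from_records([("chr1", 90_000, 110_000),
                                          ("chr1", 95_000, 105_000)], cs),
        "far": IntervalSet.from_records([("chr1", 500_000, 501_000),
                                         ("chr1", 600_000, 601_000)], cs)}
    res = distance_to_borders(groups, _pts([("chr1", 100_000)]))
    assert (res.distances["span"] == 0).all()
    assert (res.distances["far"] > 0).all()


def test_identical_groups_p_near_one():
    cs = ChromSizes({"chr1": 10**6})
    ivs = [("chr1", 10_000 * i + 1000, 10_000 * i + 2000) for i in range(12)]
    groups = {"a": IntervalSet.from_records(ivs, cs),
              "b": IntervalSet.from_records(ivs, cs)}
    res = distance_to_borders(groups, _pts([("chr1", 0)]))
    assert res.pairwise["p"].iloc[0] > 0.9


def _oracle_mwu_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for grp in combinations(range(len(pooled)), n1):
        u = ranks[list(grp)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def test_small_sample_mwu_matches_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        y = rng.integers(0, 6, size=n2).astype(float)
        _, p = mannwhitney_u(x, y)
        assert p == pytest.approx(_oracle_mwu_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# Fisher


def test_fisher_zero_margin_p_one():
    assert fisher_exact([[0, 0], [3, 5]])[1] == 1.0


def test_fisher_transpose_symmetry():
    t = [[7, 2], [3, 9]]
    assert fisher_exact(t)[1] == pytest.approx(
        fisher_exact(np.array(t).T)[1], abs=1e-12)


def _oracle_fisher_p(table):
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x) * comb(r2, c1 - x)) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def test_fisher_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(100):
        t = rng.integers(0, 16, size=(2, 2))
        _, p = fisher_exact(t)
        assert p == pytest.approx(_oracle_fisher_p(t), abs=1e-12)


def test_fisher_negative_counts_error():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [2, 3]])


# ---------------------------------------------------------------------------
# loop contacts


def _loop_setup():
    cs = ChromSizes({"chr1": 10**6})
    loops = pd.DataFrame({
        "chrom1": ["chr1"], "start1": [100_000], "end1": [110_000],
        "chrom2": ["chr1"], "start2": [500_000], "end2": [510_000]})
    genes = IntervalSet.from_records([("chr1", 502_000, 506_000, "g1")], cs)
    return cs, loops, genes


def test_te_in_anchor_gene_in_partner_is_contact():
    cs, loops, genes = _loop_setup()
    tes = {"marked": IntervalSet.from_records([("chr1", 104_000, 105_000)], cs),
           "unmarked": IntervalSet.from_records([("chr1", 700_000, 701_000)], cs)}
    res = loop_gene_contacts(tes, loops, genes, chromsizes=cs)
    assert res.fractions["marked"] == 1.0
    assert res.fractions["unmarked"] == 0.0


def test_empty_loops_all_fractions_zero_p_one():
    cs, _, genes = _loop_setup()
    empty = pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2",
                                  "start2", "end2"])
    tes = {"a": IntervalSet.from_records([("chr1", 0, 1000)], cs),
           "b": IntervalSet.from_records([("chr1", 2000, 3000)], cs)}
    res = loop_gene_contacts(tes, empty, genes, chromsizes=cs)
    assert (res.fractions == 0).all()
    assert res.tables[0].p == 1.0


def test_contact_table_p_matches_enumeration(bundle):
    from tecre import io as tio

    genes_iset = tio.genes_to_intervalset(bundle.genes, bundle.chromsizes)
    marked, unmarked = bundle.te_sets_by_truth("H4K16ac")
    # small subgroups keep the enumeration oracle cheap
    tes = {"m": marked.subset(np.arange(len(marked)) < 15),
           "u": unmarked.subset(np.arange(len(unmarked)) < 15)}
    res = loop_gene_contacts(tes, bundle.loops, genes_iset,
                             chromsizes=bundle.chromsizes)
    t = res.tables[0]
    assert t.p == pytest.approx(_oracle_fisher_p(t.table), abs=1e-12)


def test_planted_loops_separate_marked_from_unmarked():
    """With loop probability 0.4 for marked vs 0.05 for unmarked TEs at
    ~500 TEs per group, Fisher's p is < 0.01 in >=95% of seeds."""
    from tecre import io as tio
    from tecre.simulate import MarkSpec, SimConfig, TeFamilySpec, simulate

    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = SimConfig(
            seed=seed,
            te_specs=(TeFamilySpec("L1HS", "LINE", "L1", 1000, 1500.0,
                                   full_length_fraction=0.5),),
            mark_specs=(MarkSpec("H4K16ac", p_mark={"L1HS": 0.5}),))
        b = simulate(cfg)
        marked, unmarked = b.te_sets_by_truth("H4K16ac")
        genes_iset = tio.genes_to_intervalset(b.genes, b.chromsizes)
        res = loop_gene_contacts({"m": marked, "u": unmarked}, b.loops,
                                 genes_iset, chromsizes=b.chromsizes)
        assert res.fractions["m"] > res.fractions["u"]
        if res.tables[0].p < 0.01:
            hits += 1
    assert hits / n_seeds >= 0.95
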