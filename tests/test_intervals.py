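"""Interval model, BED I/O, and the overlap/closest/shuffle/merge/sample
primitives, each checked against brute-force oracles on randomized fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tecre import io as tio
from tecre.intervals import (ChromSizes, GenomicInterval, IntervalSet,
                             closest_distance, intersect_any, matched_shuffle,
                             merge_intervals, sample_intervals)

from conftest import random_intervalset


# ---------------------------------------------------------------------------
# parsing


def test_minimal_bed3_line(tmp_path, toy_chromsizes):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\n")
    iset = tio.read_bed(p, toy_chromsizes)
    (iv,) = list(iset)
    assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 200, ".")


def test_bed6_strand_preserved(tmp_path, toy_chromsizes):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\tpeak1\t7.5\t-\n")
    (iv,) = list(tio.read_bed(p, toy_chromsizes))
    assert iv.strand == "-" and iv.name == "peak1" and iv.score == 7.5


def test_unknown_chromosome_dropped_with_count(tmp_path, toy_chromsizes):
    lines = ["chr1\t0\t10", "chrUn_alt\t5\t50", "chr2\t100\t300",
             "chr1\t20\t25", "chr2\t0\t1"]
    p = tmp_path / "a.bed"
    p.write_text("\n".join(lines) + "\n")
    iset = tio.read_bed(p, toy_chromsizes)
    assert len(iset) == 4  # hand count of known-chromosome records
    assert iset.n_dropped == 1


@pytest.mark.parametrize("line", ["chr1\t100", "chr1\tx\t200", "chr1\t200\t100"])
def test_malformed_bed_names_line_number(tmp_path, toy_chromsizes, line):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t10\n" + line + "\n")
    with pytest.raises(tio.BedParseError, match=":2"):
        tio.read_bed(p, toy_chromsizes)


def test_bed_roundtrip_identity(tmp_path, toy_chromsizes):
    rng = np.random.default_rng(0)
    a = random_intervalset(rng, 80, toy_chromsizes, named=True)
    a.df.loc[::3, "strand"] = "-"
    a = IntervalSet(a.df, chromsizes=toy_chromsizes)
    p = tmp_path / "rt.bed"
    tio.write_bed(a, p)
    b = tio.read_bed(p, toy_chromsizes)
    pd.testing.assert_frame_equal(
        a.df[["chrom", "start", "end", "strand", "name"]],
        b.df[["chrom", "start", "end", "strand", "name"]])


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        ChromSizes({"chr1": 0})
    with pytest.raises(ValueError):
        IntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                  "end": [99999]}),
                    chromsizes=ChromSizes({"chr1": 100}))


# ---------------------------------------------------------------------------
# overlap semantics (half-open convention)


def test_one_bp_overlap_counts(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 0, 10)], toy_chromsizes)
    b = IntervalSet.from_records([("chr1", 9, 20)], toy_chromsizes)
    assert len(intersect_any(a, b)) == 1


def test_abutting_intervals_do_not_overlap(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 0, 10)], toy_chromsizes)
    b = IntervalSet.from_records([("chr1", 10, 20)], toy_chromsizes)
    assert len(intersect_any(a, b)) == 0


def _brute_overlaps(a_row, b_df):
    return bool(((b_df["chrom"] == a_row.chrom) & (b_df["start"] < a_row.end)
                 & (b_df["end"] > a_row.start)).any())


def test_intersect_any_matches_allpairs_oracle(toy_chromsizes):
    rng = np.random.default_rng(1)
    for _ in range(25):
        a = random_intervalset(rng, 200, toy_chromsizes)
        b = random_intervalset(rng, 200, toy_chromsizes)
        got = intersect_any(a, b).df
        expected = a.df[[_brute_overlaps(r, b.df)
                         for r in a.df.itertuples(index=False)]]
        pd.testing.assert_frame_equal(got.reset_index(drop=True),
                                      expected.reset_index(drop=True))


# ---------------------------------------------------------------------------
# closest


def test_closest_overlap_gap_zero(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 100, 200)], toy_chromsizes)
    b = IntervalSet.from_records([("chr1", 150, 160)], toy_chromsizes)
    assert closest_distance(a, b)["distance"].iloc[0] == 0


def test_closest_gap_arithmetic(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 100, 200)], toy_chromsizes)
    b = IntervalSet.from_records([("chr1", 250, 260)], toy_chromsizes)
    assert closest_distance(a, b)["distance"].iloc[0] == 50


def test_closest_empty_b_errors(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 0, 10)], toy_chromsizes)
    b = a.subset([False])
    with pytest.raises(ValueError):
        closest_distance(a, b)


def test_closest_absent_chromosome_marker(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 0, 10), ("chr2", 0, 10)],
                                 toy_chromsizes)
    b = IntervalSet.from_records([("chr1", 50, 60)], toy_chromsizes)
    res = closest_distance(a, b)
    assert res.loc[res["chrom"] == "chr2", "distance"].isna().all()


def test_closest_matches_bruteforce_minimum(toy_chromsizes):
    rng = np.random.default_rng(2)
    for _ in range(25):
        a = random_intervalset(rng, 120, toy_chromsizes)
        b = random_intervalset(rng, 120, toy_chromsizes)
        res = closest_distance(a, b)
        for row, got in zip(a.df.itertuples(index=False), res["distance"]):
            sub = b.df[b.df["chrom"] == row.chrom]
            if sub.empty:
                assert np.isnan(got)
                continue
            gaps = np.maximum(0, np.maximum(sub["start"] - row.end,
                                            row.start - sub["end"]))
            assert got == gaps.min()


# ---------------------------------------------------------------------------
# shuffle


def test_shuffle_preserves_chrom_and_length(toy_chromsizes):
    rng = np.random.default_rng(3)
    a = random_intervalset(rng, 150, toy_chromsizes)
    s = matched_shuffle(a, toy_chromsizes, seed=11)
    key = lambda df: sorted(zip(df["chrom"], df["end"] - df["start"]))
    assert key(s.df) == key(a.df)


def test_shuffle_seed_reproducible_and_seeds_differ(toy_chromsizes):
    rng = np.random.default_rng(4)
    a = random_intervalset(rng, 100, toy_chromsizes)
    s1 = matched_shuffle(a, toy_chromsizes, seed=5)
    s2 = matched_shuffle(a, toy_chromsizes, seed=5)
    s3 = matched_shuffle(a, toy_chromsizes, seed=6)
    pd.testing.assert_frame_equal(s1.df, s2.df)
    assert not s1.df["start"].equals(s3.df["start"])


def test_shuffle_degenerate_full_chromosome_placement():
    cs = ChromSizes({"chr1": 500})
    a = IntervalSet.from_records([("chr1", 0, 500)], cs)
    s = matched_shuffle(a, cs, seed=0)
    assert s.df["start"].iloc[0] == 0 and s.df["end"].iloc[0] == 500


def test_shuffle_longer_than_chromosome_errors():
    cs = ChromSizes({"chr1": 100})
    a = IntervalSet.from_records([("chr1", 0, 150)], ChromSizes({"chr1": 200}))
    with pytest.raises(ValueError):
        matched_shuffle(a, cs, seed=0)


def test_shuffle_start_distribution_uniform():
    """One length-100 interval on a 1 kb chromosome: starts uniform on
    [0, 900] over many independent shuffles (chi-square GOF)."""
    cs = ChromSizes({"chr1": 1000})
    a = IntervalSet.from_records([("chr1", 0, 100)], cs)
    rng = np.random.default_rng(7)
    starts = np.array([
        matched_shuffle(a, cs, seed=0, rng=rng).df["start"].iloc[0]
        for _ in range(10_000)])
    assert starts.min() >= 0 and starts.max() <= 900
    counts, edges = np.histogram(starts, bins=7, range=(0, 901))
    expected = np.diff(edges) / 901 * len(starts)
    p = stats.chisquare(counts, expected).pvalue
    assert p > 0.01


# ---------------------------------------------------------------------------
# merge


def test_merge_union_and_identity(toy_chromsizes):
    a = IntervalSet.from_records([("chr1", 0, 10), ("chr1", 5, 20)],
                                 toy_chromsizes)
    assert merge_intervals(a).df[["start", "end"]].values.tolist() == [[0, 20]]
    disjoint = IntervalSet.from_records([("chr1", 0, 10), ("chr1", 50, 60)],
                                        toy_chromsizes)
    pd.testing.assert_frame_equal(
        merge_intervals(disjoint).df[["chrom", "start", "end"]],
        disjoint.df[["chrom", "start", "end"]])


def test_merge_matches_bruteforce_union(toy_chromsizes):
    rng = np.random.default_rng(8)
    for _ in range(25):
        a = random_intervalset(rng, 150, toy_chromsizes)
        merged = merge_intervals(a)
        # oracle: per-bp coverage mask
        for chrom in toy_chromsizes:
            mask = np.zeros(toy_chromsizes[chrom], dtype=bool)
            for r in a.df[a.df["chrom"] == chrom].itertuples(index=False):
                mask[r.start:r.end] = True
            runs = []
            in_run = False
            for i, v in enumerate(mask):
                if v and not in_run:
                    start, in_run = i, True
                elif not v and in_run:
                    runs.append((start, i))
                    in_run = False
            if in_run:
                runs.append((start, len(mask)))
            got = merged.df[merged.df["chrom"] == chrom][["start", "end"]]
            assert [tuple(r) for r in got.values] == runs


# ---------------------------------------------------------------------------
# sample


def test_sample_full_and_empty(toy_chromsizes):
    rng = np.random.default_rng(9)
    a = random_intervalset(rng, 30, toy_chromsizes)
    full = sample_intervals(a, len(a), seed=0)
    pd.testing.assert_frame_equal(full.df, a.df)
    assert len(sample_intervals(a, 0, seed=0)) == 0
    with pytest.raises(ValueError):
        sample_intervals(a, 31, seed=0)


def test_sample_inclusion_frequency_binomial(toy_chromsizes):
    """Sampling 50 of 100 repeatedly: every member's inclusion frequency sits
    in the binomial band around 0.5."""
    rng = np.random.default_rng(10)
    a = random_intervalset(rng, 100, toy_chromsizes, named=True)
    n_rep = 2000
    freq = np.zeros(len(a))
    srng = np.random.default_rng(11)
    for _ in range(n_rep):
        s = sample_intervals(a, 50, seed=0, rng=srng)
        freq += np.isin(a.df["name"], s.df["name"])
    freq /= n_rep
    band = 4 * np.sqrt(0.25 / n_rep)  # ~4 sd
    assert ((freq > 0.5 - band) & (freq < 0.5 + band)).all()
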