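"""Genomic interval data model and the set primitives every stage builds on.

All coordinates are 0-based half-open (BED convention). One-based formats
(rmsk-style tables, GTF) are converted at the parser boundary in
:mod:`tecre.io`. Abutting intervals never count as overlapping anywhere in
the package; :func:`merge_intervals` unions book-ended runs by explicit
contract, which is a union operation, not an overlap test.
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the backing frame
COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

STRANDS = {"+", "-", "."}


class ChromSizes(Mapping):
    """Chromosome name -> length (bp). Governs interval validation and shuffling."""

    def __init__(self, entries: Mapping[str, int]):
        clean: dict[str, int] = {}
        for name, length in entries.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in clean:
                raise ValueError(f"duplicate chromosome {name!r}")
            clean[str(name)] = length
        self._entries = clean

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"])))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._entries.items():
                fh.write(f"{name}\t{length}\n")

    def __getitem__(self, key: str) -> int:
        return self._entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"ChromSizes({self._entries!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """A single stranded interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of intervals backed by a pandas DataFrame.

    After construction the set is *canonical*: sorted by (chrom, start, end)
    with a fresh integer index. ``chromsizes``, when given, bounds-checks
    every interval.
    """

    def __init__(self, df: pd.DataFrame, chromsizes: Optional[ChromSizes] = None,
                 provenance: str = ""):
        df = df.copy()
        for col, default in (("name", "."), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[COLUMNS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["strand"] = df["strand"].astype(str)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        if not df["strand"].isin(STRANDS).all():
            raise ValueError("invalid strand value in interval set")
        if chromsizes is not None:
            unknown = ~df["chrom"].isin(chromsizes.keys())
            if unknown.any():
                raise ValueError(
                    f"{int(unknown.sum())} interval(s) on chromosomes absent from "
                    "ChromSizes; drop them before constructing the set")
            lengths = df["chrom"].map(dict(chromsizes))
            if (df["end"] > lengths).any():
                bad = df[df["end"] > lengths].iloc[0]
                raise ValueError(
                    f"interval {bad['chrom']}:{bad['start']}-{bad['end']} exceeds "
                    "chromosome length")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        self.chromsizes = chromsizes
        self.provenance = provenance

    @classmethod
    def from_records(cls, records, chromsizes=None, provenance=""):
        """Build from an iterable of (chrom, start, end[, name[, score[, strand]]])
        tuples or GenomicInterval objects."""
        rows = []
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rows.append((rec.chrom, rec.start, rec.end, rec.name, rec.score,
                             rec.strand))
            else:
                rec = tuple(rec)
                rows.append(rec + (".", np.nan, ".")[len(rec) - 3:])
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df, chromsizes=chromsizes, provenance=provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            score = None if pd.isna(row.score) else float(row.score)
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand, row.name, score)

    def __repr__(self) -> str:
        src = f", provenance={self.provenance!r}" if self.provenance else ""
        return f"IntervalSet(n={len(self)}{src})"

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df[np.asarray(mask)], chromsizes=self.chromsizes,
                           provenance=self.provenance)


# ---------------------------------------------------------------------------
# set primitives


def _by_chrom(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {chrom: sub for chrom, sub in df.groupby("chrom", sort=False)}


def overlap_mask(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean per member of ``a`` (canonical order): overlaps >=1 bp of ``b``."""
    mask = np.zeros(len(a), dtype=bool)
    b_chroms = _by_chrom(b.df)
    for chrom, sub in a.df.groupby("chrom", sort=False):
        bsub = b_chroms.get(chrom)
        if bsub is None:
            continue
        # b is canonical (start-sorted); prefix max of ends gives, for every
        # prefix of b, the furthest right edge seen so far.
        b_starts = bsub["start"].to_numpy()
        b_prefix_end = np.maximum.accumulate(bsub["end"].to_numpy())
        idx = np.searchsorted(b_starts, sub["end"].to_numpy(), side="left")
        hit = (idx > 0) & (b_prefix_end[np.maximum(idx - 1, 0)] > sub["start"].to_numpy())
        mask[sub.index.to_numpy()] = hit
    return mask


def intersect_any(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Members of ``a`` overlapping >=1 bp with >=1 member of ``b``.

    bedtools ``intersect -wa -u`` semantics: each member of ``a`` appears at
    most once regardless of how many members of ``b`` it hits.
    """
    return a.subset(overlap_mask(a, b))


def closest_distance(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """Nearest member of ``b`` for every member of ``a``.

    Returns a frame aligned with ``a``'s canonical order carrying the query
    coordinates, the nearest ``b`` coordinates (NaN when ``b`` has no entry
    on the query chromosome) and ``distance``: 0 on overlap, else the number
    of bp strictly between the two intervals. Ties break toward the smaller
    ``b`` start.
    """
    if len(b) == 0:
        raise ValueError("closest_distance: b is empty")
    n = len(a)
    out_start = np.full(n, np.nan)
    out_end = np.full(n, np.nan)
    out_name = np.full(n, None, dtype=object)
    out_dist = np.full(n, np.nan)
    b_chroms = _by_chrom(b.df)
    for chrom, sub in a.df.groupby("chrom", sort=False):
        bsub = b_chroms.get(chrom)
        if bsub is None:
            continue
        bs = bsub["start"].to_numpy()
        be = bsub["end"].to_numpy()
        bn = bsub["name"].to_numpy()
        for i, s, e in zip(sub.index.to_numpy(), sub["start"].to_numpy(),
                           sub["end"].to_numpy()):
            gaps = np.maximum(0, np.maximum(bs - e, s - be))
            j = int(np.argmin(gaps))  # argmin takes the first minimum;
            # b is start-sorted, so the first minimum has the smallest start
            out_start[i] = bs[j]
            out_end[i] = be[j]
            out_name[i] = bn[j]
            out_dist[i] = gaps[j]
    res = a.df[["chrom", "start", "end", "name"]].copy()
    res["b_start"] = out_start
    res["b_end"] = out_end
    res["b_name"] = out_name
    res["distance"] = out_dist
    return res


def matched_shuffle(a: IntervalSet, chromsizes: ChromSizes, seed: int,
                    rng: Optional[np.random.Generator] = None) -> IntervalSet:
    """Randomize interval positions preserving each interval's chromosome and
    length — the enrichment null ("number, length, and chromosome ID matched").

    Starts are uniform on ``[0, chromlen - length]`` inclusive, independent
    across intervals; shuffled intervals may overlap each other. Deterministic
    given ``seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    df = a.df.copy()
    lengths = (df["end"] - df["start"]).to_numpy()
    chromlen = df["chrom"].map(dict(chromsizes)).to_numpy()
    if (lengths > chromlen).any():
        bad = df[lengths > chromlen].iloc[0]
        raise ValueError(
            f"interval {bad['chrom']}:{bad['start']}-{bad['end']} longer than its "
            "chromosome; cannot shuffle")
    starts = rng.integers(0, chromlen - lengths + 1)
    df["start"] = starts
    df["end"] = starts + lengths
    return IntervalSet(df, chromsizes=chromsizes, provenance="matched_shuffle")


def merge_intervals(a: IntervalSet) -> IntervalSet:
    """Union overlapping or book-ended members per chromosome.

    Output is disjoint (no two output intervals on one chromosome overlap or
    abut) and canonical; names/scores/strands are not propagated.
    """
    rows = []
    for chrom, sub in a.df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):  # already start-sorted
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df, chromsizes=a.chromsizes, provenance="merge")


def sample_intervals(a: IntervalSet, n: int, seed: int,
                     rng: Optional[np.random.Generator] = None) -> IntervalSet:
    """Uniform without-replacement sample of ``n`` members (bedtools sample)."""
    if n > len(a):
        raise ValueError(f"cannot sample {n} from {len(a)} intervals")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return a.subset(np.zeros(len(a), dtype=bool))
    keep = rng.choice(len(a), size=n, replace=False)
    mask = np.zeros(len(a), dtype=bool)
    mask[keep] = True
    return a.subset(mask)
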