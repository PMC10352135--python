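"""Readers and writers for the plain-text formats the pipeline consumes.

BED/BEDPE are 0-based half-open and pass through unchanged. rmsk-style TE
tables and GTF are 1-based inclusive and are converted to the internal
0-based half-open convention here, at the boundary. Records on chromosomes
absent from the governing ChromSizes are dropped with a logged count, never
an error: public annotation files routinely carry alt contigs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ChromSizes, IntervalSet

logger = logging.getLogger(__name__)


class BedParseError(ValueError):
    """Malformed record; message names the offending line number."""


def _drop_unknown(df: pd.DataFrame, chromsizes: ChromSizes | None, what: str,
                  chrom_cols=("chrom",)) -> tuple[pd.DataFrame, int]:
    if chromsizes is None:
        return df, 0
    known = np.ones(len(df), dtype=bool)
    for col in chrom_cols:
        known &= df[col].isin(chromsizes.keys()).to_numpy()
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.warning("%s: dropped %d record(s) on chromosomes absent from "
                       "ChromSizes", what, n_dropped)
    return df[known], n_dropped


def read_bed(path, chromsizes: ChromSizes | None = None) -> IntervalSet:
    """Parse BED3/BED6 into an IntervalSet (canonical order).

    The number of records dropped for unknown chromosomes is attached to the
    returned set as ``n_dropped``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates") from None
            if not 0 <= start < end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 else "."
            score = np.nan
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in {"+", "-", "."}:
                raise BedParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand"])
    df, n_dropped = _drop_unknown(df, chromsizes, str(path))
    out = IntervalSet(df, chromsizes=chromsizes, provenance=str(path))
    out.n_dropped = n_dropped
    return out


def write_bed(a: IntervalSet, path) -> None:
    """Write BED6 (BED3 plus name/score/strand; score '.' when absent)."""
    df = a.df.copy()
    df["score"] = df["score"].map(lambda v: "." if pd.isna(v) else f"{v:g}")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path, chromsizes: ChromSizes | None = None) -> pd.DataFrame:
    """Parse BEDPE loop records into a frame with chrom1..end2 (+name/score).

    Anchors are canonicalized so anchor1 is upstream of anchor2; interchromosomal
    records raise, since chromatin loops are intrachromosomal by definition here.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom1", "start1", "end1", "chrom2", "start2",
                            "end2", "name", "score"][: _ncols(path)],
                     dtype={"chrom1": str, "chrom2": str})
    if (df["chrom1"] != df["chrom2"]).any():
        raise ValueError(f"{path}: interchromosomal loop record")
    swap = df["start1"] > df["start2"]
    if swap.any():
        cols1 = ["start1", "end1"]
        cols2 = ["start2", "end2"]
        tmp = df.loc[swap, cols1].to_numpy()
        df.loc[swap, cols1] = df.loc[swap, cols2].to_numpy()
        df.loc[swap, cols2] = tmp
    df, _ = _drop_unknown(df, chromsizes, str(path), chrom_cols=("chrom1",))
    return df.reset_index(drop=True)


def _ncols(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return min(len(line.rstrip("\n").split("\t")), 8)
    return 6


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                        "name", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_rmsk(path, chromsizes: ChromSizes | None = None) -> pd.DataFrame:
    """Parse an rmsk-dialect TE table.

    Expected tab-separated columns (with header): chrom, start, end, strand,
    repName, repClass, repFamily — start 1-based inclusive, converted to
    0-based half-open here. Returns a frame with columns chrom, start, end,
    strand, name (repName), rep_class, rep_family.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "strand", "repName", "repClass",
                "repFamily"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing rmsk columns {sorted(missing)}")
    df = df.rename(columns={"repName": "name", "repClass": "rep_class",
                            "repFamily": "rep_family"})
    df["start"] = df["start"].astype(np.int64) - 1  # 1-based -> 0-based
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: invalid rmsk coordinates after conversion")
    df, _ = _drop_unknown(df, chromsizes, str(path))
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    cols = ["chrom", "start", "end", "strand", "name", "rep_class", "rep_family"]
    return df[cols].reset_index(drop=True)


def write_rmsk(df: pd.DataFrame, path) -> None:
    """Inverse of read_rmsk (emits 1-based starts)."""
    out = df.rename(columns={"name": "repName", "rep_class": "repClass",
                             "rep_family": "repFamily"}).copy()
    out["start"] = out["start"] + 1
    cols = ["chrom", "start", "end", "strand", "repName", "repClass", "repFamily"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_gtf_genes(path, chromsizes: ChromSizes | None = None) -> pd.DataFrame:
    """Extract gene models from a GTF.

    Returns one row per gene_id: chrom, start, end (gene span, 0-based
    half-open), strand, tss (strand-aware transcription start, 0-based
    position), exonic_length (bp of the union of the gene's exons — the
    feature length RPKM divides by).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    for gene in db.features_of_type("gene"):
        exons = [(e.start - 1, e.end) for e in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        exonic = _union_length(exons)
        start, end = gene.start - 1, gene.end
        tss = start if gene.strand != "-" else end - 1
        rows.append((gene.id, gene.seqid, start, end, gene.strand or ".", tss,
                     exonic))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "tss", "exonic_length"])
    df, _ = _drop_unknown(df, chromsizes, str(path))
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    return df.reset_index(drop=True)


def _union_length(blocks: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(blocks):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def genes_to_intervalset(genes: pd.DataFrame,
                         chromsizes: ChromSizes | None = None) -> IntervalSet:
    """Gene-body IntervalSet from a read_gtf_genes frame."""
    df = genes.rename(columns={"gene_id": "name"})[
        ["chrom", "start", "end", "name", "strand"]]
    return IntervalSet(df, chromsizes=chromsizes, provenance="genes")


def read_domains(path, chromsizes: ChromSizes | None = None) -> pd.DataFrame:
    """Parse a contact-domain list: TSV with columns chrom, start, end, score
    (Arrowhead-style corner score; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing domain columns {sorted(missing)}")
    df, _ = _drop_unknown(df, chromsizes, str(path))
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    return df[["chrom", "start", "end", "score"]].reset_index(drop=True)


def write_domains(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", index=False)


def read_counts(path) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Parse an expression count table.

    TSV layout: feature_id, length, then one column per sample; a final row
    with feature_id ``__library_size__`` carries per-sample library sizes
    (total mapped reads). Returns (counts, lengths, library_sizes).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "__library_size__" not in df.index:
        raise ValueError(f"{path}: missing __library_size__ row")
    lib = df.loc["__library_size__"].drop(labels=["length"]).astype(np.int64)
    df = df.drop(index="__library_size__")
    lengths = df["length"].astype(np.int64)
    counts = df.drop(columns=["length"]).astype(np.int64)
    return counts, lengths, lib


def write_counts(counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series,
                 path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths)
    tail = pd.DataFrame([[0] + list(lib_sizes)], index=["__library_size__"],
                        columns=out.columns)
    pd.concat([out, tail]).to_csv(path, sep="\t", index_label="feature_id")
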