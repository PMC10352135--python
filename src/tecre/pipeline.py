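"""End-to-end orchestration: synthetic bundle or user files in, one output
directory of plain-text tables out, with a manifest recording every seed,
parameter and input checksum.

A single master seed deterministically derives per-stage seeds by hashing
the stage name, so any stage can be re-run in isolation and reproduce the
full run's output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .chromatin3d import (borders_to_frame, distance_to_borders, domain_borders,
                          loop_gene_contacts, robust_borders)
from .expression import (DistanceBinSpec, ExpressionTable, assign_distance_bins,
                         group_rank_test, log10_rpkm)
from .intervals import ChromSizes, IntervalSet
from .peaks import PeakSet, reproducible_peaks
from .simulate import SimBundle, SimConfig, simulate
from .te_enrichment import (ElementClassConfig, TEAnnotation,
                            build_element_classes, enrichment_table)
from .tfbs import TfbsCatalog, diff_sum_scores, marked_te_set

logger = logging.getLogger(__name__)

STAGES = ("consensus", "enrichment", "tfbs", "tad", "loops", "expression")


@dataclass
class RunConfig:
    """Everything a run needs: either a SimConfig (synthetic mode) or a map
    of input file paths (file mode), plus stage toggles and thresholds."""

    seed: int = 0
    sim: SimConfig | None = None
    inputs: dict = field(default_factory=dict)  # file mode paths
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    min_support: int = 2
    n_shuffles: int = 100
    tfbs_draws: int = 20
    score_threshold: float = 1.0
    max_gap: int = 10_000
    bin_edges: tuple[int, ...] = (0, 10_000, 25_000, 50_000)
    element_config: ElementClassConfig = field(default_factory=ElementClassConfig)
    primary_mark: str = "H4K16ac"

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)


class StageError(RuntimeError):
    """An error in one pipeline stage, named."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _load_file_mode(config: RunConfig):
    """Read all file-mode inputs into the in-memory structures the stages use."""
    paths = config.inputs
    chromsizes = ChromSizes.from_file(paths["chromsizes"])
    te = TEAnnotation(tio.read_rmsk(paths["rmsk"], chromsizes), chromsizes)
    peaks: dict[str, dict[str, IntervalSet]] = {}
    for key, p in paths.get("peaks", {}).items():
        mark, rep = key
        peaks.setdefault(mark, {})[rep] = tio.read_bed(p, chromsizes)
    tfbs = tio.read_bed(paths["tfbs"], chromsizes) if "tfbs" in paths else None
    dom_a = tio.read_domains(paths["domains_a"], chromsizes) \
        if "domains_a" in paths else None
    dom_b = tio.read_domains(paths["domains_b"], chromsizes) \
        if "domains_b" in paths else None
    loops = tio.read_bedpe(paths["loops"], chromsizes) if "loops" in paths else None
    genes = tio.read_gtf_genes(paths["genes"], chromsizes) \
        if "genes" in paths else None
    counts = lengths = lib = None
    if "counts" in paths:
        counts, lengths, lib = tio.read_counts(paths["counts"])
    return dict(chromsizes=chromsizes, te=te, peaks=peaks, tfbs=tfbs,
                domains_a=dom_a, domains_b=dom_b, loops=loops, genes=genes,
                counts=counts, lengths=lengths, lib_sizes=lib)


def run_all(config: RunConfig, outdir) -> dict:
    """Run every enabled stage; returns the manifest (also written as JSON).

    Output inventory (all TSV/BED under ``outdir``): consensus_<mark>.bed,
    enrichment.tsv, tfbs_scores.tsv, robust_borders.tsv/.bed,
    border_distance.tsv, loop_contacts.tsv, expression_bins.tsv,
    expression_tests.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
                      "parameters": {
                          "min_support": config.min_support,
                          "n_shuffles": config.n_shuffles,
                          "tfbs_draws": config.tfbs_draws,
                          "score_threshold": config.score_threshold,
                          "max_gap": config.max_gap,
                          "bin_edges": list(config.bin_edges),
                          "primary_mark": config.primary_mark,
                      },
                      "mode": "synthetic" if config.sim is not None else "files",
                      "outputs": {}, "inputs": {}}

    if config.sim is not None:
        sim_cfg = config.sim
        if sim_cfg.seed != config.seed:
            sim_cfg = SimConfig(**{**_as_dict(sim_cfg), "seed": config.seed})
        bundle = simulate(sim_cfg)
        inputs_dir = outdir / "inputs"
        written = bundle.write(inputs_dir)
        manifest["inputs"] = {k: _checksum(p) for k, p in written.items()}
        data = dict(chromsizes=bundle.chromsizes, te=bundle.te_annotation,
                    peaks=bundle.peaks, tfbs=bundle.tfbs,
                    domains_a=bundle.domains_a, domains_b=bundle.domains_b,
                    loops=bundle.loops, genes=bundle.genes,
                    counts=bundle.counts, lengths=bundle.lengths,
                    lib_sizes=bundle.lib_sizes)
    else:
        data = _load_file_mode(config)
        manifest["inputs"] = {str(k): _checksum(Path(v))
                              for k, v in _flatten(config.inputs)}

    consensus = {}
    if config.stages.get("consensus", True):
        if not data["peaks"]:
            raise StageError("consensus", "no replicate peak sets")
        for mark, reps in data["peaks"].items():
            sets = [PeakSet(mark=mark, replicate=r, intervals=s)
                    for r, s in sorted(reps.items())]
            cp = reproducible_peaks(sets, min_support=config.min_support)
            consensus[mark] = cp
            path = outdir / f"consensus_{mark}.bed"
            tio.write_bed(cp.intervals, path)
            manifest["outputs"][f"consensus_{mark}"] = path.name

    classes = None
    if config.stages.get("enrichment", True) or config.stages.get("tfbs", True) \
            or config.stages.get("tad", True) or config.stages.get("loops", True):
        if data["genes"] is None:
            raise StageError("enrichment", "gene annotation required")
        classes = build_element_classes(data["te"], data["genes"],
                                        config.element_config,
                                        data["chromsizes"])

    if config.stages.get("enrichment", True):
        _require(consensus, "enrichment", "consensus stage disabled or empty")
        table = enrichment_table(consensus, classes, data["chromsizes"],
                                 n_shuffles=config.n_shuffles,
                                 seed=config.stage_seed("enrichment"))
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["outputs"]["enrichment"] = "enrichment.tsv"

    if config.stages.get("tfbs", True):
        _require(consensus, "tfbs", "consensus stage disabled or empty")
        if data["tfbs"] is None:
            raise StageError("tfbs", "no TFBS catalog")
        catalog = TfbsCatalog(data["tfbs"])
        frames = []
        for mark, cp in sorted(consensus.items()):
            for label in ("full_length_L1", "LTR_ERV", "SINE_Alu"):
                marked = marked_te_set(classes[label], cp)
                if len(marked) == 0:
                    logger.warning("tfbs: no %s TEs marked by %s", label, mark)
                    continue
                frames.append(diff_sum_scores(
                    catalog, marked, data["chromsizes"],
                    seed=config.stage_seed("tfbs"), n_draws=config.tfbs_draws,
                    te_class=label, mark=mark))
        scores = pd.concat(frames, ignore_index=True)
        scores.to_csv(outdir / "tfbs_scores.tsv", sep="\t", index=False)
        manifest["outputs"]["tfbs_scores"] = "tfbs_scores.tsv"

    borders = None
    if config.stages.get("tad", True):
        if data["domains_a"] is None or data["domains_b"] is None:
            raise StageError("tad", "two replicate domain lists required")
        pts_a = domain_borders(data["domains_a"], config.score_threshold)
        pts_b = domain_borders(data["domains_b"], config.score_threshold)
        borders = robust_borders(pts_a, pts_b, max_gap=config.max_gap)
        bframe = borders_to_frame(borders)
        bframe.to_csv(outdir / "robust_borders.tsv", sep="\t", index=False)
        bed = bframe.copy()
        bed["end"] = bed["pos"] + 1
        bed[["chrom", "pos", "end"]].to_csv(outdir / "robust_borders.bed",
                                            sep="\t", header=False, index=False)
        manifest["outputs"]["robust_borders"] = "robust_borders.tsv"
        _require(consensus, "tad", "consensus stage disabled or empty")
        cp = consensus.get(config.primary_mark)
        if cp is not None and borders:
            groups = _marked_unmarked_groups(classes, cp, config.primary_mark)
            if len(groups) >= 2:
                res = distance_to_borders(groups, borders)
                rows = [{"group": g, "n": len(v),
                         "median_distance": float(np.median(v))}
                        for g, v in res.distances.items()]
                summary = pd.DataFrame(rows)
                summary.to_csv(outdir / "border_distance_groups.tsv", sep="\t",
                               index=False)
                res.pairwise.to_csv(outdir / "border_distance.tsv", sep="\t",
                                    index=False)
                manifest["outputs"]["border_distance"] = "border_distance.tsv"

    if config.stages.get("loops", True):
        if data["loops"] is None:
            raise StageError("loops", "no loop list")
        _require(consensus, "loops", "consensus stage disabled or empty")
        cp = consensus.get(config.primary_mark)
        if cp is None:
            raise StageError("loops", f"no consensus for {config.primary_mark}")
        groups = _marked_unmarked_groups(classes, cp, config.primary_mark)
        genes_iset = tio.genes_to_intervalset(data["genes"], data["chromsizes"])
        res = loop_gene_contacts(groups, data["loops"], genes_iset,
                                 chromsizes=data["chromsizes"])
        rows = [{"group": g, "n": int(res.sizes[g]),
                 "contacting": int(res.counts[g]),
                 "fraction": float(res.fractions[g])} for g in res.fractions.index]
        pd.DataFrame(rows).to_csv(outdir / "loop_contact_groups.tsv", sep="\t",
                                  index=False)
        trows = [{"group_a": t.group_a, "group_b": t.group_b,
                  "odds_ratio": t.odds_ratio, "p": t.p} for t in res.tables]
        pd.DataFrame(trows).to_csv(outdir / "loop_contacts.tsv", sep="\t",
                                   index=False)
        manifest["outputs"]["loop_contacts"] = "loop_contacts.tsv"

    if config.stages.get("expression", True):
        if data["counts"] is None:
            raise StageError("expression", "no count table")
        _require(consensus, "expression", "consensus stage disabled or empty")
        cp = consensus.get(config.primary_mark)
        if cp is None:
            raise StageError("expression",
                             f"no consensus for {config.primary_mark}")
        marked = marked_te_set(
            ElementClassStub("all_te", data["te"].to_intervalset()), cp)
        table = ExpressionTable(counts=data["counts"], lengths=data["lengths"],
                                lib_sizes=data["lib_sizes"])
        genes_iset = tio.genes_to_intervalset(data["genes"], data["chromsizes"])
        spec = DistanceBinSpec(edges=config.bin_edges)
        bins = assign_distance_bins(genes_iset, marked, spec)
        expr = log10_rpkm(table).mean(axis=1)
        per_gene = pd.DataFrame({"gene_id": bins.index, "bin": bins.to_numpy(),
                                 "log10_rpkm": expr.reindex(bins.index).to_numpy()})
        per_gene.to_csv(outdir / "expression_bins.tsv", sep="\t", index=False)
        grouped = {label: per_gene.loc[per_gene["bin"] == label,
                                       "log10_rpkm"].to_numpy()
                   for label in spec.labels}
        grouped = {k: v for k, v in grouped.items() if len(v) >= 2}
        if len(grouped) >= 2:
            res = group_rank_test(grouped)
            head = pd.DataFrame([{"statistic": "kruskal_wallis_H", "value": res.h},
                                 {"statistic": "kruskal_wallis_p", "value": res.p}])
            out = pd.concat(
                [head, res.pairwise.assign(statistic="dunn")],
                ignore_index=True)
            out.to_csv(outdir / "expression_tests.tsv", sep="\t", index=False)
            manifest["outputs"]["expression_tests"] = "expression_tests.tsv"
        manifest["outputs"]["expression_bins"] = "expression_bins.tsv"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclass
class ElementClassStub:
    label: str
    intervals: IntervalSet


def _marked_unmarked_groups(classes, cp, mark: str) -> dict[str, IntervalSet]:
    """Marked/unmarked split of the LTR class (the primary 3D comparison),
    falling back to the full-length L1 class when the annotation has no LTRs."""
    out = {}
    for label in ("LTR_ERV", "full_length_L1"):
        base = classes[label].intervals
        if len(base) == 0:
            continue
        from .intervals import overlap_mask  # local import avoids cycle noise
        hit = overlap_mask(base, cp.intervals)
        if hit.any() and (~hit).any():
            out[f"{label}_{mark}+"] = base.subset(hit)
            out[f"{label}_{mark}-"] = base.subset(~hit)
            break
    return out


def _require(obj, stage: str, message: str):
    if not obj:
        raise StageError(stage, message)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _flatten(d, prefix=""):
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            yield from _flatten(v, f"{key}.")
        else:
            yield key, v


def _as_dict(cfg) -> dict:
    import dataclasses
    return {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)}
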