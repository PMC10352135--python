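"""(Diff/Sum) TF-binding-site enrichment at mark-positive TEs.

For one (TE class, mark) cell, TFBS records overlapping the marked TEs are
counted per TF and converted to a percentage distribution across TFs; the
same is done inside chromosome/length-matched random bins; and the score is

    S = (p_obs - p_exp) / (p_obs + p_exp),

bounded in [-1, 1], 0 at the null point p_obs = p_exp (and by convention
when both are 0), +1 when a TF appears only at marked TEs, -1 when only in
the random background. Counting is record-level: a TFBS record counts once
however many TEs it overlaps. The percentage normalization runs across TFs
within one cell, so each side is a distribution over TFs summing to 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ChromSizes, IntervalSet, intersect_any, matched_shuffle, overlap_mask
from .peaks import ConsensusPeaks
from .te_enrichment import ElementClass

logger = logging.getLogger(__name__)


@dataclass
class TfbsCatalog:
    """TFBS-cluster intervals; the ``name`` of each record is the TF."""

    intervals: IntervalSet

    def __post_init__(self):
        names = self.intervals.df["name"]
        if (names == ".").any() or (names == "").any():
            raise ValueError("TfbsCatalog records must carry a TF name")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.intervals.df["name"].unique())


def marked_te_set(te_class: ElementClass,
                  consensus: ConsensusPeaks | IntervalSet) -> IntervalSet:
    """TEs of a class overlapping >=1 consensus peak (mark-positive TEs)."""
    peaks = (consensus.intervals if isinstance(consensus, ConsensusPeaks)
             else consensus)
    return intersect_any(te_class.intervals, peaks)


def diff_sum(p_obs: float, p_exp: float) -> float:
    """The (Diff/Sum) score on a pair of percentages; 0 when both vanish."""
    total = p_obs + p_exp
    if total == 0:
        return 0.0
    return (p_obs - p_exp) / total


def _counts_per_tf(tfbs: TfbsCatalog, target: IntervalSet,
                   tfs: list[str]) -> pd.Series:
    hit = overlap_mask(tfbs.intervals, target)
    counts = tfbs.intervals.df.loc[hit, "name"].value_counts()
    return counts.reindex(tfs, fill_value=0).astype(float)


def _percentages(counts: pd.Series) -> pd.Series:
    total = counts.sum()
    if total == 0:
        return counts * 0.0
    return counts / total * 100.0


def diff_sum_scores(tfbs: TfbsCatalog, marked: IntervalSet,
                    chromsizes: ChromSizes, seed: int = 0,
                    n_draws: int = 20, te_class: str = "",
                    mark: str = "") -> pd.DataFrame:
    """Per-TF (Diff/Sum) scores of a marked TE set against matched random bins.

    The expected side averages TFBS counts over ``n_draws`` matched-shuffle
    draws of the marked set before converting to percentages; ``n_draws=1``
    is the literal single-randomization procedure. Returns a frame with
    columns tf, te_class, mark, obs_count, exp_count, obs_pct, exp_pct, score.
    """
    if len(marked) == 0:
        raise ValueError("marked TE set is empty")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    tfs = tfbs.tfs
    obs_counts = _counts_per_tf(tfbs, marked, tfs)
    rng = np.random.default_rng(seed)
    exp_counts = pd.Series(0.0, index=tfs)
    for _ in range(n_draws):
        bins = matched_shuffle(marked, chromsizes, seed=0, rng=rng)
        exp_counts += _counts_per_tf(tfbs, bins, tfs)
    exp_counts /= n_draws
    if obs_counts.sum() == 0 and exp_counts.sum() == 0:
        logger.warning("no TFBS overlap either side; all scores 0")
    obs_pct = _percentages(obs_counts)
    exp_pct = _percentages(exp_counts)
    rows = []
    for tf in tfs:
        rows.append({
            "tf": tf, "te_class": te_class, "mark": mark,
            "obs_count": float(obs_counts[tf]), "exp_count": float(exp_counts[tf]),
            "obs_pct": float(obs_pct[tf]), "exp_pct": float(exp_pct[tf]),
            "score": diff_sum(float(obs_pct[tf]), float(exp_pct[tf])),
        })
    return pd.DataFrame(rows)
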