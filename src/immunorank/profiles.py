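"""Rank-based expression (RBE) curves and per-group profile statistics.

For one probe set and one cell group, the rank scores of all group samples
form a distribution over the scores ``1..n_bins``.  The RBE curve is that
distribution normalized to sample fractions: ordinate[s] = (number of group
samples whose score is s) / (group size), so the ordinates always sum to 1.
A narrow curve means the probe set sits at a stable expression percentile
across all the group's experimental conditions; a wide or multi-modal curve
means its expression is plastic.

Two summary statistics condense each curve:

* **GPL** (gene plasticity score) — the interquartile range Q3 − Q1 of the
  group's rank scores.  High GPL = variable expression under diverse
  conditions; GPL 0 = at least half the samples share one score.
* **ARS** (average rank score) — the arithmetic mean of the group's rank
  scores.  Very small or very large ARS suggests stably low or high
  expression, the signature of a marker candidate.

Quartiles use linear interpolation between order statistics with the p-th
quantile at position 1 + (n − 1)p in the sorted scores (numpy's default,
R's type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .compendium import SampleRecord
from .ranking import RankScoreMatrix

__all__ = ["RBECurve", "rbe_curve", "profile_stats", "overall_profile_stats",
           "plot_rbe_curves"]


@dataclass
class RBECurve:
    """Distribution of one probe set's rank scores within one cell group.

    ``ordinates[s - 1]`` is the fraction of group samples with rank score
    ``s``; the vector has length ``n_bins`` and sums to 1.
    """

    probe_set_id: str
    cell_group: str
    ordinates: np.ndarray
    n_samples: int

    @property
    def n_bins(self) -> int:
        return self.ordinates.size

    def ordinate(self, score: int) -> float:
        """Sample fraction at a rank score (1-based)."""
        if not 1 <= score <= self.n_bins:
            raise ValueError(f"score {score} outside [1, {self.n_bins}]")
        return float(self.ordinates[score - 1])


def _group_sample_ids(samples: Iterable[SampleRecord] | pd.DataFrame,
                      cell_group: str) -> list[str]:
    if isinstance(samples, pd.DataFrame):
        mask = samples["cell_group"] == cell_group
        return list(samples.loc[mask, "sample_id"])
    return [s.sample_id for s in samples if s.cell_group == cell_group]


def _group_scores(ranks: RankScoreMatrix,
                  samples: Iterable[SampleRecord] | pd.DataFrame,
                  cell_group: str) -> pd.DataFrame:
    ids = _group_sample_ids(samples, cell_group)
    if not ids:
        raise ValueError(f"cell group {cell_group!r} has no samples")
    missing = [i for i in ids if i not in ranks.scores.columns]
    if missing:
        raise ValueError(f"group samples absent from rank matrix: {missing}")
    return ranks.scores[ids]


def rbe_curve(ranks: RankScoreMatrix,
              samples: Iterable[SampleRecord] | pd.DataFrame,
              probe_set_id: str,
              cell_group: str) -> RBECurve:
    """Build the RBE curve of one probe set in one cell group.

    Raises on an unknown probe set or an empty group.
    """
    group = _group_scores(ranks, samples, cell_group)
    if probe_set_id not in group.index:
        raise KeyError(f"unknown probe set: {probe_set_id!r}")
    scores = group.loc[probe_set_id].to_numpy()
    counts = np.bincount(scores, minlength=ranks.n_bins + 1)[1:]
    return RBECurve(probe_set_id=probe_set_id, cell_group=cell_group,
                    ordinates=counts / scores.size, n_samples=scores.size)


def profile_stats(ranks: RankScoreMatrix,
                  samples: Iterable[SampleRecord] | pd.DataFrame,
                  cell_group: str) -> pd.DataFrame:
    """Per-probe GPL, ARS and quartiles within one cell group.

    Returns a DataFrame with one row per probe set and columns
    ``probe_set_id, cell_group, n_samples, q1, q3, gpl, ars``.
    """
    group = _group_scores(ranks, samples, cell_group)
    values = group.to_numpy(dtype=float)
    q1, q3 = np.percentile(values, [25, 75], axis=1)
    return pd.DataFrame({
        "probe_set_id": group.index,
        "cell_group": cell_group,
        "n_samples": values.shape[1],
        "q1": q1,
        "q3": q3,
        "gpl": q3 - q1,
        "ars": values.mean(axis=1),
    }).reset_index(drop=True)


def overall_profile_stats(ranks: RankScoreMatrix) -> pd.DataFrame:
    """GPL/ARS/quartiles of each probe set over the whole compendium."""
    values = ranks.scores.to_numpy(dtype=float)
    q1, q3 = np.percentile(values, [25, 75], axis=1)
    return pd.DataFrame({
        "probe_set_id": ranks.scores.index,
        "cell_group": "(all)",
        "n_samples": values.shape[1],
        "q1": q1,
        "q3": q3,
        "gpl": q3 - q1,
        "ars": values.mean(axis=1),
    }).reset_index(drop=True)


def plot_rbe_curves(curves: Sequence[RBECurve], out_path: Optional[str] = None,
                    ax=None):
    """Overlay RBE curves on one axes; save to ``out_path`` if given."""
    import matplotlib
    if out_path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for curve in curves:
        xs = np.arange(1, curve.n_bins + 1)
        ax.plot(xs, curve.ordinates,
                label=f"{curve.probe_set_id} / {curve.cell_group} "
                      f"(n={curve.n_samples})")
    ax.set_xlabel("rank score")
    ax.set_ylabel("sample ratio")
    ax.legend(fontsize=8)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
    return ax
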