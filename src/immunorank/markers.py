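"""Signed marker evaluation score (MES) from Wilcoxon rank-sum tests.

For a probe set *j* the background vector holds its rank scores across ALL
samples of ALL cell groups; each cell group *i* contributes its own score
vector.  A two-sided Wilcoxon rank-sum (Mann-Whitney U) test compares the
group against the background, and

    MES = |log10 p|, signed positive when median(group) >= median(background)
    MES = NA        when p underflows to 0 or the background is constant

A large positive MES marks a probe set whose expression percentile in the
group sits reliably above its compendium-wide behaviour — the statistical
signature of a marker.  Note the group is included in its own background
(the background is defined over all cell groups with no exclusion), which
pulls MES toward 0 for groups that dominate the compendium.

The p-value uses scipy's asymptotic normal approximation with tie and
continuity corrections; when the pooled sample is small enough that the
rank-sum null can be enumerated cheaply (at most ``EXACT_LIMIT``
group/background splits) the exact permutation distribution is used
instead, so small toy problems get exact p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .compendium import SampleRecord
from .profiles import _group_sample_ids
from .ranking import RankScoreMatrix

__all__ = ["MESRecord", "background_matrix", "mes", "mes_table", "EXACT_LIMIT"]

# exact permutation enumeration is used when C(n_group + n_background, n_group)
# is at most this; covers every pooled size <= 16 (C(16,8) = 12,870)
EXACT_LIMIT = 50_000


@dataclass(frozen=True)
class MESRecord:
    """MES of one (probe set, cell group) pair.

    ``mes`` is ``None`` (serialized "NA") when the p-value underflowed to
    zero or the background scores were all identical.
    """

    probe_set_id: str
    cell_group: str
    mes: Optional[float]
    p_value: float
    group_median: float
    background_median: float
    n_group: int
    n_background: int

    @property
    def is_na(self) -> bool:
        return self.mes is None


def background_matrix(ranks: RankScoreMatrix, probe_set_id: str) -> np.ndarray:
    """Rank scores of one probe set across all samples of all groups."""
    return ranks.probe_scores(probe_set_id).to_numpy()


def _use_exact(n_group: int, n_background: int) -> bool:
    return math.comb(n_group + n_background, n_group) <= EXACT_LIMIT


def _rank_sum_p(group: np.ndarray, background: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small pooled samples)."""
    if _use_exact(group.size, background.size):
        method = stats.PermutationMethod(n_resamples=np.inf)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(group, background, alternative="two-sided",
                             method=method, use_continuity=True)
    return float(res.pvalue)


def _signed_mes(p_value: float, group_median: float,
                background_median: float) -> Optional[float]:
    if p_value == 0.0:
        return None
    magnitude = abs(math.log10(p_value))
    return magnitude if group_median >= background_median else -magnitude


def mes(ranks: RankScoreMatrix,
        samples: Iterable[SampleRecord] | pd.DataFrame,
        probe_set_id: str,
        cell_group: str) -> MESRecord:
    """MES of one probe set in one cell group against the full background."""
    background = background_matrix(ranks, probe_set_id)
    group_ids = _group_sample_ids(samples, cell_group)
    if not group_ids:
        raise ValueError(f"cell group {cell_group!r} has no samples")
    group = ranks.scores.loc[probe_set_id, group_ids].to_numpy()

    group_median = float(np.median(group))
    background_median = float(np.median(background))
    if np.all(background == background[0]):
        return MESRecord(probe_set_id, cell_group, None, float("nan"),
                         group_median, background_median,
                         group.size, background.size)
    p_value = _rank_sum_p(group, background)
    return MESRecord(probe_set_id, cell_group,
                     _signed_mes(p_value, group_median, background_median),
                     p_value, group_median, background_median,
                     group.size, background.size)


def mes_table(ranks: RankScoreMatrix,
              samples: Iterable[SampleRecord] | pd.DataFrame) -> pd.DataFrame:
    """MES of every (probe set, cell group) pair.

    Equivalent to calling :func:`mes` pairwise but vectorized across probe
    sets within each group.  Returns columns ``probe_set_id, cell_group,
    n_group, n_background, group_median, background_median, p_value, mes``
    with ``mes`` NaN where the record is NA.
    """
    if isinstance(samples, pd.DataFrame):
        sample_df = samples
    else:
        sample_df = pd.DataFrame(
            [(s.sample_id, s.cell_group) for s in samples],
            columns=["sample_id", "cell_group"])
    groups = sorted(sample_df["cell_group"].unique())
    if not groups:
        raise ValueError("no cell groups present")

    all_scores = ranks.scores.to_numpy(dtype=float)
    bg_median = np.median(all_scores, axis=1)
    bg_constant = np.all(all_scores == all_scores[:, :1], axis=1)
    n_background = all_scores.shape[1]

    frames = []
    for cell_group in groups:
        ids = _group_sample_ids(sample_df, cell_group)
        cols = [ranks.scores.columns.get_loc(i) for i in ids]
        group_scores = all_scores[:, cols]
        n_group = group_scores.shape[1]
        g_median = np.median(group_scores, axis=1)

        if _use_exact(n_group, n_background):
            p = np.array([_rank_sum_p(group_scores[i], all_scores[i])
                          for i in range(all_scores.shape[0])])
        else:
            res = stats.mannwhitneyu(group_scores, all_scores,
                                     alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=True, axis=1)
            p = np.asarray(res.pvalue, dtype=float)

        with np.errstate(divide="ignore"):
            magnitude = np.abs(np.log10(p))
        signed = np.where(g_median >= bg_median, magnitude, -magnitude)
        na = bg_constant | (p == 0.0)
        signed = np.where(na, np.nan, signed)
        p_out = np.where(bg_constant, np.nan, p)

        frames.append(pd.DataFrame({
            "probe_set_id": ranks.scores.index,
            "cell_group": cell_group,
            "n_group": n_group,
            "n_background": n_background,
            "group_median": g_median,
            "background_median": bg_median,
            "p_value": p_out,
            "mes": signed,
        }))
    return pd.concat(frames, ignore_index=True)
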