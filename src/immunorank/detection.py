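"""Detection-call calibration: a rank-score cut-off for undetectable expression.

Affymetrix arrays label every (probe set, sample) cell present (P), marginal
(M) or absent (A).  Pooling those calls over a compendium and stratifying by
rank score gives, for each score ``s``, the fraction of cells called absent.
Low scores are dominated by absent calls; the calibrated threshold is the
score below which the absent fraction stays at or above a target (default
0.99), i.e. the rank score under which expression can be treated as
undetectable (hybridisation noise).  Marginal calls count as not-absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ranking import RankScoreMatrix

__all__ = ["DetectionCallTable", "CalibrationResult",
           "absent_fraction_by_score", "calibrate_threshold", "calibrate",
           "read_detection_calls"]

_VALID_CALLS = {"P", "M", "A"}


@dataclass
class DetectionCallTable:
    """P/M/A call per (probe set, sample); indices match a rank matrix."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.calls.to_numpy(dtype=str)
        bad = set(np.unique(values)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")


@dataclass
class CalibrationResult:
    """Absent fraction per score and the calibrated cut-off.

    ``threshold`` is the largest ``t`` such that every score below ``t`` has
    an absent fraction at or above ``target_fraction`` (1 when no score
    qualifies).  When every score qualifies the threshold saturates at
    ``n_bins`` and ``saturated`` is set.
    """

    absent_fraction: np.ndarray  # NaN where a score has no cells
    threshold: int
    target_fraction: float
    saturated: bool = False


def read_detection_calls(path) -> DetectionCallTable:
    """Read a calls TSV shaped like signals.tsv with P/M/A entries."""
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls.index = calls.index.astype(str)
    calls.index.name = "probe_set_id"
    return DetectionCallTable(calls)


def _check_aligned(calls: DetectionCallTable, ranks: RankScoreMatrix) -> None:
    if (not calls.calls.index.equals(ranks.scores.index)
            or not calls.calls.columns.equals(ranks.scores.columns)):
        raise ValueError("detection-call table and rank matrix indices differ")


def absent_fraction_by_score(calls: DetectionCallTable,
                             ranks: RankScoreMatrix) -> np.ndarray:
    """Fraction of cells called absent at each rank score 1..n_bins.

    Entry ``s - 1`` is the fraction of (probe set, sample) cells with rank
    score ``s`` whose call is A; scores with no cells yield NaN.
    """
    _check_aligned(calls, ranks)
    scores = ranks.scores.to_numpy().ravel()
    absent = (calls.calls.to_numpy(dtype=str) == "A").ravel()
    totals = np.bincount(scores, minlength=ranks.n_bins + 1)[1:]
    absents = np.bincount(scores, weights=absent, minlength=ranks.n_bins + 1)[1:]
    with np.errstate(invalid="ignore"):
        return np.where(totals > 0, absents / np.maximum(totals, 1), np.nan)


def calibrate_threshold(absent_fraction: np.ndarray,
                        target_fraction: float = 0.99) -> CalibrationResult:
    """Largest threshold t with absent fraction >= target at every score < t.

    A score with no cells (NaN fraction) breaks the qualifying run.  If the
    run covers every score the threshold saturates at ``n_bins``.
    """
    fractions = np.asarray(absent_fraction, dtype=float)
    finite = fractions[np.isfinite(fractions)]
    if finite.size and ((finite < 0) | (finite > 1)).any():
        raise ValueError("absent fractions must lie in [0, 1]")
    n_bins = fractions.size
    threshold = 1
    for s in range(n_bins):
        if np.isfinite(fractions[s]) and fractions[s] >= target_fraction:
            threshold = s + 2  # all scores < s+2 qualify
        else:
            break
    saturated = threshold == n_bins + 1
    if saturated:
        threshold = n_bins
    return CalibrationResult(absent_fraction=fractions, threshold=threshold,
                             target_fraction=target_fraction,
                             saturated=saturated)


def calibrate(calls: DetectionCallTable, ranks: RankScoreMatrix,
              target_fraction: float = 0.99,
              cell_group: Optional[list[str]] = None) -> CalibrationResult:
    """One-step calibration: absent fractions, then the threshold.

    ``cell_group`` optionally restricts the pooled cells to the given
    sample IDs' columns (callers pass a group's sample IDs); default pools
    the whole compendium.
    """
    if cell_group is not None:
        calls = DetectionCallTable(calls.calls[cell_group])
        ranks = RankScoreMatrix(scores=ranks.scores[cell_group],
                                n_bins=ranks.n_bins)
    fractions = absent_fraction_by_score(calls, ranks)
    return calibrate_threshold(fractions, target_fraction)
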