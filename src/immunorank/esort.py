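"""Electronic sorting: retrieve samples by gene-expression rank score.

Electronic sorting is the retrieval of cell states or experimental
conditions — annotated samples — whose rank score for a chosen probe set
falls in a chosen score window within a cell group.  Because rank scores
are comparable across arrays, a window like [95, 100] picks out the
conditions under which the gene sits in the top percentiles of its array,
whatever the absolute signal scale.  Results come in two views: per sample
(one row per hit, with signal, score and annotation) and per series (one
row per experiment submission, with hit and group totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .compendium import ExpressionCompendium, SampleRecord
from .ranking import RankScoreMatrix

__all__ = ["SortQuery", "SortHit", "SortResult", "esort", "esort_report"]


@dataclass(frozen=True)
class SortQuery:
    """A score-window query: probe set, cell group and [score_lo, score_hi]."""

    probe_set_id: str
    cell_group: str
    score_lo: int
    score_hi: int

    def __post_init__(self) -> None:
        if self.score_lo > self.score_hi:
            raise ValueError(
                f"inverted score range [{self.score_lo}, {self.score_hi}]")
        if self.score_lo < 1:
            raise ValueError("score_lo must be >= 1")


@dataclass(frozen=True)
class SortHit:
    sample: SampleRecord
    signal: float
    rank_score: int


@dataclass
class SortResult:
    """Hits of a sort query plus the per-series view.

    ``series_view`` maps each series ID to ``(hit sample IDs, total number
    of group samples in that series)``; it partitions the hits.
    """

    query: SortQuery
    hits: list[SortHit]
    series_view: dict[str, tuple[list[str], int]] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def esort(compendium: ExpressionCompendium,
          ranks: RankScoreMatrix,
          query: SortQuery) -> SortResult:
    """Run a sort query: all group samples with score in the window.

    Raises ``KeyError`` on an unknown probe set and ``ValueError`` on an
    unknown cell group or a window above ``n_bins``.
    """
    if query.score_hi > ranks.n_bins:
        raise ValueError(
            f"score_hi {query.score_hi} exceeds n_bins {ranks.n_bins}")
    if query.cell_group not in set(compendium.samples["cell_group"]):
        raise ValueError(f"unknown cell group: {query.cell_group!r}")
    probe_scores = ranks.probe_scores(query.probe_set_id)
    if query.probe_set_id not in compendium.signals.index:
        raise KeyError(f"probe set not in compendium: {query.probe_set_id!r}")
    probe_signals = compendium.signals.loc[query.probe_set_id]

    mask = compendium.samples["cell_group"] == query.cell_group
    group = compendium.samples.loc[mask]

    hits = []
    for row in group.itertuples(index=False):
        score = int(probe_scores[row.sample_id])
        if query.score_lo <= score <= query.score_hi:
            hits.append(SortHit(sample=SampleRecord(*row),
                                signal=float(probe_signals[row.sample_id]),
                                rank_score=score))

    group_counts = group["series_id"].value_counts()
    series_view: dict[str, tuple[list[str], int]] = {}
    for hit in hits:
        series_id = hit.sample.series_id
        if series_id not in series_view:
            series_view[series_id] = ([], int(group_counts[series_id]))
        series_view[series_id][0].append(hit.sample.sample_id)
    return SortResult(query=query, hits=hits, series_view=series_view)


def esort_report(result: SortResult, mode: str = "sample") -> pd.DataFrame:
    """Tabulate a sort result.

    ``mode="sample"`` gives one row per hit (sample_id, series_id, title,
    characteristics, signal, rank_score); ``mode="series"`` gives one row
    per series (series_id, n_hits, n_group_samples_in_series).
    """
    if mode == "sample":
        rows = [(h.sample.sample_id, h.sample.series_id, h.sample.title,
                 h.sample.characteristics, h.signal, h.rank_score)
                for h in result.hits]
        return pd.DataFrame(rows, columns=["sample_id", "series_id", "title",
                                           "characteristics", "signal",
                                           "rank_score"])
    if mode == "series":
        rows = [(series_id, len(sample_ids), n_in_series)
                for series_id, (sample_ids, n_in_series)
                in result.series_view.items()]
        return pd.DataFrame(rows, columns=["series_id", "n_hits",
                                           "n_group_samples_in_series"])
    raise ValueError(f"mode must be 'sample' or 'series', got {mode!r}")
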