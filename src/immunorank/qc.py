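"""Marker-based sample admission: does a sample express its type's markers?

A sample annotated as a given cell type must show detectable expression of
that type's required marker genes, e.g. a regulatory T cell sample must
express CD4 and CD25.  Detectability is a rank score at or above a
threshold (typically the calibrated undetectable-expression cut-off).  A
marker may be measured by several probe sets; any one detectable probe set
satisfies the marker, but every marker of the panel must be satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from .compendium import ExpressionCompendium
from .ranking import RankScoreMatrix

__all__ = ["MarkerRule", "MarkerPanel", "qc_filter",
           "read_marker_panel", "write_marker_panel"]


@dataclass(frozen=True)
class MarkerRule:
    """One required marker of one cell group.

    ``threshold`` overrides the panel-wide detection threshold when set.
    """

    cell_group: str
    marker_name: str
    probe_set_ids: tuple[str, ...]
    threshold: int | None = None

    def __post_init__(self) -> None:
        if not self.probe_set_ids:
            raise ValueError(
                f"marker {self.marker_name!r} ({self.cell_group!r}) "
                "names no probe sets")


@dataclass
class MarkerPanel:
    """Required markers per cell group plus the default detection threshold."""

    rules: list[MarkerRule]
    detect_threshold: int = 25

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("panel has no marker rules")

    @property
    def cell_groups(self) -> list[str]:
        return sorted({r.cell_group for r in self.rules})

    def rules_for(self, cell_group: str) -> list[MarkerRule]:
        return [r for r in self.rules if r.cell_group == cell_group]

    def threshold_for(self, rule: MarkerRule) -> int:
        return rule.threshold if rule.threshold is not None else self.detect_threshold


def qc_filter(compendium: ExpressionCompendium,
              ranks: RankScoreMatrix,
              panel: MarkerPanel) -> tuple[list[str], list[tuple[str, str]]]:
    """Split panel-covered samples into kept and rejected.

    A sample is kept iff, for every marker rule of its cell group, at least
    one of the marker's probe sets has rank score >= the rule's threshold.
    Rejected samples carry the first failing marker (panel order).  Samples
    whose group has no panel rules are neither kept nor rejected.

    Returns ``(kept sample IDs, [(sample ID, failed marker name), ...])``.
    """
    known_probes = set(ranks.scores.index)
    for rule in panel.rules:
        unknown = [p for p in rule.probe_set_ids if p not in known_probes]
        if unknown:
            raise ValueError(
                f"panel marker {rule.marker_name!r} references unknown "
                f"probe sets: {unknown}")
    covered = set(panel.cell_groups)
    kept: list[str] = []
    rejected: list[tuple[str, str]] = []
    for row in compendium.samples.itertuples(index=False):
        if row.cell_group not in covered:
            continue
        failed = None
        for rule in panel.rules_for(row.cell_group):
            threshold = panel.threshold_for(rule)
            detected = any(
                int(ranks.scores.at[p, row.sample_id]) >= threshold
                for p in rule.probe_set_ids)
            if not detected:
                failed = rule.marker_name
                break
        if failed is None:
            kept.append(row.sample_id)
        else:
            rejected.append((row.sample_id, failed))
    return kept, rejected


def read_marker_panel(path: Union[str, Path],
                      detect_threshold: int = 25) -> MarkerPanel:
    """Read a panel TSV (cell_group, marker_name, probe_set_ids, threshold).

    ``probe_set_ids`` is pipe-separated; an empty ``threshold`` falls back
    to ``detect_threshold``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rules = []
    for row in table.itertuples(index=False):
        threshold = int(row.threshold) if str(row.threshold).strip() else None
        rules.append(MarkerRule(
            cell_group=row.cell_group,
            marker_name=row.marker_name,
            probe_set_ids=tuple(p for p in row.probe_set_ids.split("|") if p),
            threshold=threshold))
    return MarkerPanel(rules=rules, detect_threshold=detect_threshold)


def write_marker_panel(panel: MarkerPanel, path: Union[str, Path]) -> None:
    rows = [(r.cell_group, r.marker_name, "|".join(r.probe_set_ids),
             "" if r.threshold is None else r.threshold)
            for r in panel.rules]
    pd.DataFrame(rows, columns=["cell_group", "marker_name", "probe_set_ids",
                                "threshold"]).to_csv(path, sep="\t", index=False)
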