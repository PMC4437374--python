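"""Synthetic annotated expression compendia with planted ground truth.

The generator emulates a curated immune-cell microarray compendium: several
cell groups, each with tens of samples spread over a few series, a
log-normal (heavy-tailed, positive) background signal matrix, and a set of
planted genes whose rank-score behaviour is engineered:

* ``marker_high(group)`` — scores inside a high band (default [90, 100]) in
  the focal group, a low band elsewhere: a specific, stable marker.
* ``marker_low(group)`` — mirrored: low in the focal group, high elsewhere.
* ``plastic_bimodal(group, high_fraction)`` — within the focal group a
  fraction of samples sit in a high band and the rest in a low band,
  producing a two-peaked distribution with a large interquartile range.
* ``disease_shift(group_hi, group_lo)`` — high in one group, low in its
  partner, mid-range elsewhere: a disease-associated expression shift.

Plants are engineered in signal space but targeted in rank space: for each
sample a global ascending rank position is drawn inside the target score
block and the planted signal is placed exactly between the background order
statistics bracketing that position, so after ranking the realized score
falls in the requested band by construction.  The generator still ranks and
verifies every plant, failing loudly rather than degrading ground truth.

The generator also plants QC violators (samples whose own group's marker
probes are forced into an undetectable band) and detection calls that are
absent with high probability below a cutoff score, so marker evaluation,
sample QC and detection calibration all have recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium, write_compendium
from .detection import DetectionCallTable
from .qc import MarkerPanel, MarkerRule, write_marker_panel
from .ranking import block_sizes, rank_scores_for_compendium

__all__ = ["AbsentModel", "PlantedGene", "SyntheticSpec", "GroundTruth",
           "SyntheticDataset", "default_spec", "generate",
           "write_synthetic_dataset"]

# score bands used by the default plants
HIGH_BAND = (90, 100)
LOW_BAND = (4, 14)
MID_BAND = (40, 60)
VIOLATION_BAND = (1, 10)


@dataclass(frozen=True)
class AbsentModel:
    """Detection-call geometry: P(absent) below vs at-or-above the cutoff."""

    cutoff_score: int = 25
    absent_prob_below: float = 0.995
    absent_prob_above: float = 0.005
    marginal_prob: float = 0.02  # among non-absent cells


@dataclass(frozen=True)
class PlantedGene:
    """One engineered probe set.

    ``groups`` holds the focal group (or the (high, low) pair for
    ``disease_shift``); ``band`` is the target score band in the focal
    group.  ``qc_marker`` plants are wired into the marker panel and are
    the ones QC violators break.
    """

    probe_set_id: str
    pattern: str  # marker_high | marker_low | plastic_bimodal | disease_shift
    groups: tuple[str, ...]
    band: tuple[int, int] = HIGH_BAND
    high_fraction: float = 0.5
    qc_marker: bool = False
    marker_name: str = ""

    def __post_init__(self) -> None:
        if self.pattern not in {"marker_high", "marker_low",
                                "plastic_bimodal", "disease_shift"}:
            raise ValueError(f"unknown pattern: {self.pattern!r}")
        if self.pattern == "disease_shift" and len(self.groups) != 2:
            raise ValueError("disease_shift needs a (high, low) group pair")
        if self.band[0] > self.band[1] or self.band[0] < 1:
            raise ValueError(f"invalid band {self.band}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Construction parameters of a synthetic compendium."""

    n_probes: int = 2000
    n_samples_per_group: dict[str, int] = field(default_factory=dict)
    n_series_per_group: int = 6
    n_bins: int = 100
    seed: int = 0
    planted_genes: tuple[PlantedGene, ...] = ()
    qc_violation_fraction: float = 0.12
    absent_model: AbsentModel = AbsentModel()
    detect_threshold: int = 25
    unannotated_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_probes < self.n_bins:
            raise ValueError("n_probes must be >= n_bins")
        groups = set(self.n_samples_per_group)
        for gene in self.planted_genes:
            unknown = set(gene.groups) - groups
            if unknown:
                raise ValueError(
                    f"plant {gene.probe_set_id} references unknown groups "
                    f"{sorted(unknown)}")
            if gene.band[1] > self.n_bins:
                raise ValueError(
                    f"plant {gene.probe_set_id} band exceeds n_bins")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    planted: pd.DataFrame      # probe_set_id, pattern, groups, band, ...
    violators: list[str]       # sample IDs that must fail marker QC
    absent_model: AbsentModel
    detect_threshold: int

    def planted_by_pattern(self, pattern: str) -> pd.DataFrame:
        return self.planted[self.planted["pattern"] == pattern]


class SyntheticDataset(NamedTuple):
    compendium: ExpressionCompendium
    calls: DetectionCallTable
    panel: Optional[MarkerPanel]  # None when no plant is a QC marker
    ground_truth: GroundTruth


DEFAULT_GROUPS = ("B cell", "CD4+ T cell", "NK", "Monocyte", "PMN/neutrophil")


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default study conditions: 2,000 probes, 5 groups x 60 samples.

    Plants: one QC marker per group (two for the first group, exercising
    multi-marker panels), one extra non-QC marker, two bimodal plastic
    genes, one low-in-group marker and one disease shift pair.
    """
    groups = {g: 60 for g in DEFAULT_GROUPS}
    b, t, nk, mono, pmn = DEFAULT_GROUPS
    plants = (
        PlantedGene("MRK00001_at", "marker_high", (b,), qc_marker=True,
                    marker_name="CD19"),
        PlantedGene("MRK00002_at", "marker_high", (b,), qc_marker=True,
                    marker_name="MS4A1"),
        PlantedGene("MRK00003_at", "marker_high", (t,), qc_marker=True,
                    marker_name="CD4"),
        PlantedGene("MRK00004_at", "marker_high", (nk,), qc_marker=True,
                    marker_name="NCAM1"),
        PlantedGene("MRK00005_at", "marker_high", (mono,), qc_marker=True,
                    marker_name="CD14"),
        PlantedGene("MRK00006_at", "marker_high", (pmn,), qc_marker=True,
                    marker_name="FCGR3B"),
        PlantedGene("MRK00007_at", "marker_high", (t,), marker_name="CD247"),
        PlantedGene("PLS00001_at", "plastic_bimodal", (pmn,),
                    high_fraction=0.4, band=(88, 98), marker_name="CCL20"),
        PlantedGene("PLS00002_at", "plastic_bimodal", (mono,),
                    high_fraction=0.5, band=(88, 98), marker_name="IL6"),
        PlantedGene("LOW00001_at", "marker_low", (b,), band=(1, 10),
                    marker_name="CD3D"),
        PlantedGene("DIS00001_at", "disease_shift", (b, nk), band=(88, 98),
                    marker_name="DNTT"),
    )
    return SyntheticSpec(n_samples_per_group=groups, seed=seed,
                         planted_genes=plants)


# ---------------------------------------------------------------------------
# plant targeting
# ---------------------------------------------------------------------------

def _band_for(gene: PlantedGene, cell_group: str, is_high_sample: bool,
              violated: bool) -> tuple[int, int]:
    """Target score band of one plant for one sample."""
    if violated and gene.qc_marker and cell_group == gene.groups[0]:
        return VIOLATION_BAND
    if gene.pattern == "marker_high":
        return gene.band if cell_group == gene.groups[0] else LOW_BAND
    if gene.pattern == "marker_low":
        return gene.band if cell_group == gene.groups[0] else HIGH_BAND
    if gene.pattern == "plastic_bimodal":
        if cell_group != gene.groups[0]:
            return MID_BAND
        return gene.band if is_high_sample else (3, 12)
    # disease_shift
    if cell_group == gene.groups[0]:
        return gene.band
    if cell_group == gene.groups[1]:
        return LOW_BAND
    return MID_BAND


def _plant_positions(rng: np.random.Generator, bands: list[tuple[int, int]],
                     sizes: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Distinct global ascending-rank positions, one per plant, in-band."""
    for _ in range(200):
        positions = np.empty(len(bands), dtype=np.int64)
        for i, (lo, hi) in enumerate(bands):
            score = int(rng.integers(lo, hi + 1))
            positions[i] = starts[score - 1] + int(rng.integers(sizes[score - 1]))
        if len(np.unique(positions)) == len(positions):
            return positions
    raise RuntimeError("could not draw distinct plant positions "
                       "(band too narrow for the number of plants)")


def _planted_values(positions: np.ndarray, bg_sorted: np.ndarray) -> np.ndarray:
    """Signal values placed exactly between the bracketing order statistics."""
    m = positions.size
    n_bg = bg_sorted.size
    order = np.argsort(positions)
    gaps = positions[order] - (np.arange(m) + 1)  # background values below
    values = np.empty(m)
    i = 0
    while i < m:
        j = i
        while j + 1 < m and gaps[j + 1] == gaps[i]:
            j += 1
        k = int(gaps[i])
        lo = bg_sorted[k - 1] if k > 0 else bg_sorted[0] * 0.5
        hi = bg_sorted[k] if k < n_bg else bg_sorted[-1] * 1.5 + 1.0
        count = j - i + 1
        fracs = (np.arange(1, count + 1)) / (count + 1)
        values[order[i:j + 1]] = lo + (hi - lo) * fracs
        i = j + 1
    return values


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a compendium, detection calls, marker panel and ground truth.

    Deterministic given ``spec.seed``.  After construction the matrix is
    ranked and every plant's realized score is verified against its band;
    an infeasible plant raises instead of silently degrading ground truth.
    """
    if not spec.n_samples_per_group:
        spec = SyntheticSpec(**{**spec.__dict__,
                                "n_samples_per_group": {g: 60 for g in DEFAULT_GROUPS}})
    rng = np.random.default_rng(spec.seed)
    plants = list(spec.planted_genes)
    n_planted = len(plants)
    n_bg = spec.n_probes - n_planted
    if n_bg < spec.n_bins:
        raise ValueError("too many plants for the probe count")

    # --- samples ----------------------------------------------------------
    rows = []
    idx = 0
    for g_i, (group, n) in enumerate(spec.n_samples_per_group.items()):
        for k in range(n):
            series = f"GSE{g_i:02d}{k % spec.n_series_per_group:02d}"
            rows.append((f"GSM{idx:05d}", series, group,
                         f"{group} sample {k}",
                         f"cell type: {group}; condition: c{k % 7}"))
            idx += 1
    samples = pd.DataFrame(rows, columns=["sample_id", "series_id",
                                          "cell_group", "title",
                                          "characteristics"])
    n_samples = len(samples)

    # --- planted assignments ---------------------------------------------
    n_viol = int(round(spec.qc_violation_fraction * n_samples))
    violator_idx = rng.choice(n_samples, size=n_viol, replace=False)
    violators = sorted(samples["sample_id"].iloc[violator_idx])
    violator_set = set(violators)

    # per plastic plant: which focal-group samples are "high"
    high_sample_sets: dict[str, set[str]] = {}
    for gene in plants:
        if gene.pattern != "plastic_bimodal":
            continue
        ids = samples.loc[samples["cell_group"] == gene.groups[0], "sample_id"]
        n_high = int(round(gene.high_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_high, replace=False)
        high_sample_sets[gene.probe_set_id] = set(ids.iloc[chosen])

    # --- signals -----------------------------------------------------------
    bg_ids = [f"IMS{i:05d}_at" for i in range(n_bg)]
    probe_ids = [g.probe_set_id for g in plants] + bg_ids
    mu = rng.normal(6.0, 1.5, size=n_bg)
    noise = rng.normal(0.0, 0.4, size=(n_bg, n_samples))
    bg_signals = np.exp(mu[:, None] + noise)

    sizes = block_sizes(spec.n_probes, spec.n_bins)
    starts = np.concatenate([[1], 1 + np.cumsum(sizes)[:-1]])

    planted_signals = np.empty((n_planted, n_samples))
    for j, srow in enumerate(samples.itertuples(index=False)):
        violated = srow.sample_id in violator_set
        bands = [
            _band_for(gene, srow.cell_group,
                      srow.sample_id in high_sample_sets.get(gene.probe_set_id,
                                                             set()),
                      violated)
            for gene in plants
        ]
        positions = _plant_positions(rng, bands, sizes, starts)
        bg_sorted = np.sort(bg_signals[:, j])
        planted_signals[:, j] = _planted_values(positions, bg_sorted)

    signals = pd.DataFrame(np.vstack([planted_signals, bg_signals]),
                           index=pd.Index(probe_ids, name="probe_set_id"),
                           columns=pd.Index(samples["sample_id"].to_numpy()))

    # --- probe annotations --------------------------------------------------
    n_unannotated = int(round(spec.unannotated_fraction * n_bg))
    annotated_bg = bg_ids[:n_bg - n_unannotated] if n_unannotated else bg_ids
    probe_rows = []
    for i, gene in enumerate(plants):
        symbol = gene.marker_name or f"PLANT{i}"
        probe_rows.append((gene.probe_set_id, symbol, 900000 + i,
                           (f"{symbol}-ALT",)))
    for i, pid in enumerate(annotated_bg):
        probe_rows.append((pid, f"GENE{i:05d}", 100000 + i, ()))
    probes = pd.DataFrame(probe_rows, columns=["probe_set_id", "gene_symbol",
                                               "gene_id", "aliases"])

    compendium = ExpressionCompendium(signals=signals, samples=samples,
                                      probes=probes)

    # --- verify plants in rank space ---------------------------------------
    ranks = rank_scores_for_compendium(compendium, spec.n_bins)
    group_of = dict(zip(samples["sample_id"], samples["cell_group"]))
    for gene in plants:
        realized = ranks.scores.loc[gene.probe_set_id]
        for sample_id, score in realized.items():
            band = _band_for(
                gene, group_of[sample_id],
                sample_id in high_sample_sets.get(gene.probe_set_id, set()),
                sample_id in violator_set)
            if not band[0] <= score <= band[1]:
                raise RuntimeError(
                    f"plant {gene.probe_set_id} missed its band {band} in "
                    f"sample {sample_id} (realized {score})")

    # --- detection calls -----------------------------------------------------
    am = spec.absent_model
    score_arr = ranks.scores.to_numpy()
    p_absent = np.where(score_arr < am.cutoff_score,
                        am.absent_prob_below, am.absent_prob_above)
    u = rng.random(score_arr.shape)
    is_absent = u < p_absent
    is_marginal = ~is_absent & (rng.random(score_arr.shape) < am.marginal_prob)
    call_values = np.where(is_absent, "A", np.where(is_marginal, "M", "P"))
    calls = DetectionCallTable(pd.DataFrame(call_values,
                                            index=signals.index.copy(),
                                            columns=signals.columns.copy()))

    # --- panel and ground truth ---------------------------------------------
    rules = [MarkerRule(cell_group=g.groups[0], marker_name=g.marker_name,
                        probe_set_ids=(g.probe_set_id,))
             for g in plants if g.qc_marker]
    panel = (MarkerPanel(rules=rules, detect_threshold=spec.detect_threshold)
             if rules else None)

    planted_table = pd.DataFrame(
        [(g.probe_set_id, g.pattern, "|".join(g.groups), g.band[0], g.band[1],
          g.high_fraction, g.qc_marker, g.marker_name) for g in plants],
        columns=["probe_set_id", "pattern", "groups", "band_lo", "band_hi",
                 "high_fraction", "qc_marker", "marker_name"])
    truth = GroundTruth(planted=planted_table, violators=violators,
                        absent_model=am,
                        detect_threshold=spec.detect_threshold)
    return SyntheticDataset(compendium, calls, panel, truth)


def write_synthetic_dataset(dataset: SyntheticDataset,
                            out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write signals/samples/probes/calls/panel TSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv"
             for name in ("signals", "samples", "probes", "calls", "panel",
                          "ground_truth")}
    write_compendium(dataset.compendium, paths["signals"], paths["samples"],
                     paths["probes"])
    calls_out = dataset.calls.calls.copy()
    calls_out.index.name = "probe_set_id"
    calls_out.to_csv(paths["calls"], sep="\t")
    if dataset.panel is not None:
        write_marker_panel(dataset.panel, paths["panel"])
    else:
        del paths["panel"]
    dataset.ground_truth.planted.to_csv(paths["ground_truth"], sep="\t",
                                        index=False)
    return paths
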