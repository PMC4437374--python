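"""Annotated expression compendium: domain types and TSV readers/writers.

A compendium bundles a non-negative signal matrix (probe sets x samples)
with per-sample annotations (series membership, cell group, free text) and
per-probe-set gene annotations (symbol, numeric gene ID, aliases).  Probe
sets that carry no annotation stay in the matrix — they occupy rank
positions on the physical array — but are invisible to gene-level queries.

Interchange is plain tab-separated text:

* ``signals.tsv`` — first column ``probe_set_id``, one column per sample.
* ``samples.tsv`` — ``sample_id, series_id, cell_group, title, characteristics``.
* ``probes.tsv``  — ``probe_set_id, gene_symbol, gene_id, aliases`` (aliases
  pipe-separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "ProbeRecord",
    "ExpressionCompendium",
    "CompendiumValidationError",
    "read_compendium",
    "write_compendium",
    "resolve_gene",
]

SAMPLE_COLUMNS = ["sample_id", "series_id", "cell_group", "title", "characteristics"]
PROBE_COLUMNS = ["probe_set_id", "gene_symbol", "gene_id", "aliases"]


class CompendiumValidationError(ValueError):
    """Raised when a compendium violates a structural invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """One array: a GSM-like sample with its GSE-like series and cell group."""

    sample_id: str
    series_id: str
    cell_group: str
    title: str = ""
    characteristics: str = ""


@dataclass(frozen=True)
class ProbeRecord:
    """Gene annotation of one probe set (symbol, numeric gene ID, aliases)."""

    probe_set_id: str
    gene_symbol: str
    gene_id: int
    aliases: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class ExpressionCompendium:
    """Signal matrix plus sample and probe annotation tables.

    Parameters
    ----------
    signals
        DataFrame of finite, non-negative intensities; index = probe set IDs,
        columns = sample IDs.
    samples
        One row per sample, columns :data:`SAMPLE_COLUMNS`.
    probes
        One row per annotated probe set, columns :data:`PROBE_COLUMNS`
        (``aliases`` holds tuples of strings).  Matrix rows without a probe
        row are retained but flagged unannotated.
    """

    signals: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.probes = self.probes.reset_index(drop=True)
        _validate(self)

    # -- basic views -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def probe_set_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def cell_groups(self) -> list[str]:
        return sorted(self.samples["cell_group"].unique())

    @property
    def annotated_probe_set_ids(self) -> list[str]:
        return list(self.probes["probe_set_id"])

    def is_annotated(self, probe_set_id: str) -> bool:
        return probe_set_id in set(self.probes["probe_set_id"])

    def sample_records(self) -> Iterator[SampleRecord]:
        for row in self.samples.itertuples(index=False):
            yield SampleRecord(*row)

    def probe_records(self) -> Iterator[ProbeRecord]:
        for row in self.probes.itertuples(index=False):
            yield ProbeRecord(row.probe_set_id, row.gene_symbol,
                              int(row.gene_id), tuple(row.aliases))

    def samples_in_group(self, cell_group: str) -> list[str]:
        mask = self.samples["cell_group"] == cell_group
        return list(self.samples.loc[mask, "sample_id"])


def _validate(c: ExpressionCompendium) -> None:
    sig = c.signals
    dup_probes = sig.index[sig.index.duplicated()].unique().tolist()
    if dup_probes:
        raise CompendiumValidationError(f"duplicate probe set IDs: {dup_probes}")
    dup_samples = sig.columns[sig.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise CompendiumValidationError(f"duplicate sample IDs: {dup_samples}")

    dup_ann = c.samples["sample_id"][c.samples["sample_id"].duplicated()].tolist()
    if dup_ann:
        raise CompendiumValidationError(f"duplicate sample annotation rows: {dup_ann}")
    dup_pann = c.probes["probe_set_id"][c.probes["probe_set_id"].duplicated()].tolist()
    if dup_pann:
        raise CompendiumValidationError(f"duplicate probe annotation rows: {dup_pann}")

    matrix_samples = set(sig.columns)
    annot_samples = set(c.samples["sample_id"])
    missing = sorted(matrix_samples - annot_samples)
    if missing:
        raise CompendiumValidationError(
            f"samples in matrix missing from annotation: {missing}")
    extra = sorted(annot_samples - matrix_samples)
    if extra:
        raise CompendiumValidationError(
            f"annotated samples missing from matrix: {extra}")

    values = sig.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise CompendiumValidationError(
                f"non-numeric signal values: {exc}") from exc
    bad_mask = ~np.isfinite(values) | (values < 0)
    if bad_mask.any():
        i, j = np.argwhere(bad_mask)[0]
        raise CompendiumValidationError(
            "negative or non-finite signal at "
            f"(probe={sig.index[i]!r}, sample={sig.columns[j]!r})")

    if (c.samples["series_id"].astype(str).str.len() == 0).any():
        empty = c.samples.loc[
            c.samples["series_id"].astype(str).str.len() == 0, "sample_id"].tolist()
        raise CompendiumValidationError(f"empty series_id for samples: {empty}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_aliases(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    return tuple(a for a in (p.strip() for p in text.split("|")) if a)


def read_compendium(signals_path: Union[str, Path],
                    samples_path: Union[str, Path],
                    probes_path: Union[str, Path]) -> ExpressionCompendium:
    """Read the three TSV tables and return a validated compendium.

    Raises
    ------
    CompendiumValidationError
        On duplicate IDs, negative/non-numeric signals, or matrix samples
        absent from the annotation table (the error names the offender).
    """
    signals = pd.read_csv(signals_path, sep="\t", index_col=0,
                          float_precision="round_trip")
    signals.index = signals.index.astype(str)
    signals.columns = signals.columns.astype(str)
    signals.index.name = "probe_set_id"
    try:
        signals = signals.astype(float)
    except (TypeError, ValueError) as exc:
        raise CompendiumValidationError(f"non-numeric signal value: {exc}") from exc

    samples = pd.read_csv(samples_path, sep="\t", dtype=str,
                          keep_default_na=False)
    missing_cols = [col for col in SAMPLE_COLUMNS if col not in samples.columns]
    if missing_cols:
        raise CompendiumValidationError(
            f"samples table missing columns: {missing_cols}")
    samples = samples[SAMPLE_COLUMNS]

    probes_raw = pd.read_csv(probes_path, sep="\t", dtype=str,
                             keep_default_na=False)
    missing_cols = [col for col in PROBE_COLUMNS if col not in probes_raw.columns]
    if missing_cols:
        raise CompendiumValidationError(
            f"probes table missing columns: {missing_cols}")
    probes = pd.DataFrame({
        "probe_set_id": probes_raw["probe_set_id"],
        "gene_symbol": probes_raw["gene_symbol"],
        "gene_id": probes_raw["gene_id"].astype(int),
        "aliases": probes_raw["aliases"].map(_parse_aliases),
    })
    return ExpressionCompendium(signals=signals, samples=samples, probes=probes)


def write_compendium(compendium: ExpressionCompendium,
                     signals_path: Union[str, Path],
                     samples_path: Union[str, Path],
                     probes_path: Union[str, Path]) -> None:
    """Write the three TSV tables; ``read_compendium`` round-trips them.

    Signals are serialized with ``repr`` round-trip precision so the matrix
    survives write/read to full float64 precision.
    """
    sig = compendium.signals.copy()
    sig.index.name = "probe_set_id"
    sig.to_csv(signals_path, sep="\t", float_format="%.17g")
    compendium.samples.to_csv(samples_path, sep="\t", index=False)
    probes_out = compendium.probes.copy()
    probes_out["aliases"] = probes_out["aliases"].map("|".join)
    probes_out.to_csv(probes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene query resolution
# ---------------------------------------------------------------------------

def resolve_gene(query: Union[str, int],
                 compendium: ExpressionCompendium) -> list[str]:
    """Resolve a gene query to the matching annotated probe set IDs.

    Matching is attempted on gene symbol and aliases (case-insensitive),
    numeric gene ID (exact), and probe set ID (exact).  A probe-set-ID query
    returns exactly that probe set.  No match yields an empty list, never an
    error.  Unannotated probe sets never appear in results.
    """
    probes = compendium.probes
    if isinstance(query, int) or (isinstance(query, str) and query.isdigit()):
        gene_id = int(query)
        hits = probes.loc[probes["gene_id"] == gene_id, "probe_set_id"]
        if len(hits):
            return sorted(hits)
    text = str(query)
    exact = probes.loc[probes["probe_set_id"] == text, "probe_set_id"]
    if len(exact):
        return sorted(exact)
    folded = text.casefold()
    symbol_hit = probes["gene_symbol"].str.casefold() == folded
    alias_hit = probes["aliases"].map(
        lambda aliases: any(a.casefold() == folded for a in aliases))
    return sorted(probes.loc[symbol_hit | alias_hit, "probe_set_id"])
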