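import numpy as np
import pandas as pd
import pytest

from immunorank import (ExpressionCompendium, RankScoreMatrix,
                        rank_scores_for_compendium)
from immunorank.synthetic import SyntheticSpec, default_spec, generate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic compendium with planted ground truth."""
    return generate(default_spec(seed=0))


@pytest.fixture(scope="session")
def ranks(dataset):
    return rank_scores_for_compendium(dataset.compendium)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny two-group compendium without plants, for fast structural tests."""
    spec = SyntheticSpec(n_probes=150,
                         n_samples_per_group={"alpha": 8, "beta": 6},
                         n_series_per_group=2, n_bins=10, seed=3,
                         planted_genes=(), qc_violation_fraction=0.0)
    return generate(spec)


@pytest.fixture()
def toy_compendium():
    """Hand-built 5-probe x 4-sample compendium (2 groups, 2 series)."""
    signals = pd.DataFrame(
        np.array([[10.0, 11.0, 1.0, 2.0],
                  [5.0, 6.0, 7.0, 8.0],
                  [1.0, 2.0, 10.0, 9.0],
                  [3.0, 3.5, 4.0, 4.5],
                  [8.0, 7.5, 2.5, 3.2]]),
        index=pd.Index(["205476_at", "P2_at", "P3_at", "P4_at", "P5_at"],
                       name="probe_set_id"),
        columns=["GSM1", "GSM2", "GSM3", "GSM4"])
    samples = pd.DataFrame({
        "sample_id": ["GSM1", "GSM2", "GSM3", "GSM4"],
        "series_id": ["GSE1", "GSE1", "GSE2", "GSE2"],
        "cell_group": ["PMN", "PMN", "B cell", "B cell"],
        "title": ["pmn rest", "pmn lps", "b rest", "b stim"],
        "characteristics": ["c1", "c2", "c3", "c4"],
    })
    probes = pd.DataFrame({
        "probe_set_id": ["205476_at", "P2_at", "P3_at", "P4_at"],
        "gene_symbol": ["CCL20", "ACTB", "CD19", "GAPDH"],
        "gene_id": [6364, 60, 930, 2597],
        "aliases": [("MIP-3-alpha", "LARC"), (), ("B4",), ()],
    })  # P5_at left unannotated on purpose
    return ExpressionCompendium(signals=signals, samples=samples, probes=probes)


def make_rank_matrix(scores: np.ndarray, sample_ids=None, probe_ids=None,
                     n_bins: int = 100) -> RankScoreMatrix:
    """Wrap a raw integer array as a RankScoreMatrix for direct-score tests."""
    scores = np.atleast_2d(np.asarray(scores, dtype=int))
    n_probes, n_samples = scores.shape
    probe_ids = probe_ids or [f"PR{i}_at" for i in range(n_probes)]
    sample_ids = sample_ids or [f"GSM{j}" for j in range(n_samples)]
    frame = pd.DataFrame(scores, index=pd.Index(probe_ids, name="probe_set_id"),
                         columns=sample_ids)
    return RankScoreMatrix(scores=frame, n_bins=n_bins)


def make_samples(cell_groups, series=None) -> pd.DataFrame:
    """Sample table for a list of per-sample group labels."""
    n = len(cell_groups)
    return pd.DataFrame({
        "sample_id": [f"GSM{j}" for j in range(n)],
        "series_id": series or ["GSE0"] * n,
        "cell_group": list(cell_groups),
        "title": [""] * n,
        "characteristics": [""] * n,
    })
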