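import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from immunorank import background_matrix, mes, mes_table

from conftest import make_rank_matrix, make_samples


def exact_rank_sum_p(group, background):
    """Independent oracle: enumerate the rank-sum null over all splits.

    Two-sided p is the doubled smaller one-sided tail, capped at 1.
    """
    pooled = np.concatenate([group, background])
    ranks = sps.rankdata(pooled)
    m, n = len(group), len(pooled)
    observed = ranks[:m].sum()
    sums = np.array([ranks[list(combo)].sum()
                     for combo in itertools.combinations(range(n), m)])
    p_greater = np.mean(sums >= observed - 1e-9)
    p_less = np.mean(sums <= observed + 1e-9)
    return min(1.0, 2 * min(p_greater, p_less))


def build(group_scores, other_scores, n_bins=100):
    """One-probe rank matrix with a 'g' group and 'o' rest."""
    all_scores = list(group_scores) + list(other_scores)
    ranks = make_rank_matrix(np.array(all_scores).reshape(1, -1), n_bins=n_bins)
    samples = make_samples(["g"] * len(group_scores) + ["o"] * len(other_scores))
    return ranks, samples


def test_background_spans_all_groups():
    ranks, samples = build([9, 10, 10], [1, 1])
    assert background_matrix(ranks, "PR0_at").tolist() == [9, 10, 10, 1, 1]
    with pytest.raises(KeyError):
        background_matrix(ranks, "missing_at")


def test_single_group_background_equals_group():
    ranks, samples = build([5, 7, 9], [])
    rec = mes(ranks, samples, "PR0_at", "g")
    # self-comparison: medians equal, p near 1, tiny positive score
    assert rec.group_median == rec.background_median
    assert rec.mes is not None and rec.mes >= 0
    assert rec.mes < 0.5


def test_worked_small_sample_against_enumeration():
    """group [9,10,10] vs background [1,1,2,2,9,10,10]."""
    group = np.array([9, 10, 10])
    background = np.array([1, 1, 2, 2, 9, 10, 10])
    ranks = make_rank_matrix(np.array([[9, 10, 10, 1, 1, 2, 2]]).reshape(1, -1))
    # background must be all samples; build group=first 3, others complete it
    samples = make_samples(["g", "g", "g", "o", "o", "o", "o"])
    rec = mes(ranks, samples, "PR0_at", "g")
    expected_p = exact_rank_sum_p(group, ranks.scores.iloc[0].to_numpy())
    assert rec.p_value == pytest.approx(expected_p, rel=1e-12)
    assert rec.mes == pytest.approx(abs(math.log10(expected_p)), rel=1e-12)
    assert rec.mes > 0  # group median 10 >= background median 2


def test_exact_p_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(60):
        # group and background (all samples) both capped at 8
        n_g = int(rng.integers(2, 7))
        n_o = int(rng.integers(1, 9 - n_g))
        group = rng.integers(1, 101, size=n_g)
        others = rng.integers(1, 101, size=n_o)
        ranks, samples = build(group.tolist(), others.tolist())
        background = ranks.scores.iloc[0].to_numpy()
        if np.all(background == background[0]):
            continue
        rec = mes(ranks, samples, "PR0_at", "g")
        assert rec.p_value == pytest.approx(
            exact_rank_sum_p(group, background), rel=1e-12)
        expected_sign = 1 if np.median(group) >= np.median(background) else -1
        if rec.mes is not None and rec.mes != 0:
            assert math.copysign(1, rec.mes) == expected_sign


def test_na_on_constant_background():
    ranks, samples = build([50, 50], [50, 50, 50])
    rec = mes(ranks, samples, "PR0_at", "g")
    assert rec.is_na and rec.mes is None


def test_antisymmetry_on_disjoint_groups():
    ranks, samples = build([90, 92, 95, 97], [5, 8, 10, 12])
    high = mes(ranks, samples, "PR0_at", "g")
    low = mes(ranks, samples, "PR0_at", "o")
    assert high.mes > 0 > low.mes


def test_shifting_group_up_never_decreases_mes():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n_g, n_o = int(rng.integers(5, 25)), int(rng.integers(5, 40))
        group = rng.integers(20, 60, size=n_g)
        others = rng.integers(1, 101, size=n_o)
        shift = int(rng.integers(2, 30))
        base = mes(*build(group.tolist(), others.tolist()), "PR0_at", "g")
        shifted = mes(*build((group + shift).tolist(), others.tolist()),
                      "PR0_at", "g")
        assert shifted.mes >= base.mes - 1e-9


def test_mes_table_matches_pairwise_calls(small_dataset):
    from immunorank import rank_scores_for_compendium
    ranks = rank_scores_for_compendium(small_dataset.compendium, n_bins=10)
    samples = small_dataset.compendium.samples
    table = mes_table(ranks, samples).set_index(["probe_set_id", "cell_group"])
    assert len(table) == ranks.n_probes * 2
    rng = np.random.default_rng(3)
    for probe in rng.choice(ranks.probe_set_ids, size=12, replace=False):
        for group in ("alpha", "beta"):
            rec = mes(ranks, samples, probe, group)
            row = table.loc[(probe, group)]
            if rec.is_na:
                assert np.isnan(row.mes)
            else:
                assert row.mes == pytest.approx(rec.mes, rel=1e-9)
                assert row.p_value == pytest.approx(rec.p_value, rel=1e-9)
            assert row.group_median == rec.group_median
            assert row.background_median == rec.background_median


def test_planted_marker_sign_pattern(ranks, dataset):
    """A group-specific marker: strongly positive MES at home; away groups
    sit at or below the background median and never score high."""
    samples = dataset.compendium.samples
    home = mes(ranks, samples, "MRK00001_at", "B cell")
    assert home.mes is not None and home.mes > 5
    for group in ("CD4+ T cell", "NK", "Monocyte", "PMN/neutrophil"):
        away = mes(ranks, samples, "MRK00001_at", group)
        assert away.group_median <= away.background_median
        assert away.mes < home.mes / 2
        if away.group_median < away.background_median:
            assert away.mes < 0


def test_disease_shift_gene_signs(ranks, dataset):
    """High-in-one / low-in-another plant: positive MES where high,
    negative where low (background median sits strictly between)."""
    samples = dataset.compendium.samples
    hi = mes(ranks, samples, "DIS00001_at", "B cell")
    lo = mes(ranks, samples, "DIS00001_at", "NK")
    assert hi.mes is not None and hi.mes > 5
    assert lo.mes is not None and lo.mes < -5
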