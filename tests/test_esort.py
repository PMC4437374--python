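import numpy as np
import pytest

from immunorank import SortQuery, esort, esort_report


def brute_force_hits(compendium, ranks, query):
    """Oracle: scan every sample, keep group members with score in range."""
    hits = set()
    for row in compendium.samples.itertuples(index=False):
        if row.cell_group != query.cell_group:
            continue
        score = int(ranks.scores.at[query.probe_set_id, row.sample_id])
        if query.score_lo <= score <= query.score_hi:
            hits.add(row.sample_id)
    return hits


def hit_ids(result):
    return {h.sample.sample_id for h in result.hits}


def test_matches_brute_force_on_random_queries(dataset, ranks):
    rng = np.random.default_rng(17)
    probes = list(ranks.probe_set_ids)
    groups = dataset.compendium.cell_groups
    for _ in range(150):
        lo = int(rng.integers(1, 101))
        hi = int(rng.integers(lo, 101))
        query = SortQuery(probes[rng.integers(len(probes))],
                          groups[rng.integers(len(groups))], lo, hi)
        result = esort(dataset.compendium, ranks, query)
        assert hit_ids(result) == brute_force_hits(dataset.compendium, ranks,
                                                   query)
        for hit in result.hits:
            assert lo <= hit.rank_score <= hi


def test_full_range_returns_whole_group(dataset, ranks):
    group = "NK"
    query = SortQuery("MRK00004_at", group, 1, ranks.n_bins)
    result = esort(dataset.compendium, ranks, query)
    assert hit_ids(result) == set(dataset.compendium.samples_in_group(group))


def test_empty_range_yields_empty_result(dataset, ranks):
    # the NK marker sits in [90, 100] for nearly all NK samples; a mid score
    # bin that no NK sample occupies gives an empty result
    scores = ranks.scores.loc["MRK00004_at",
                              dataset.compendium.samples_in_group("NK")]
    missing = next(s for s in range(30, 80) if (scores != s).all())
    result = esort(dataset.compendium, ranks,
                   SortQuery("MRK00004_at", "NK", missing, missing))
    assert result.hits == [] and result.series_view == {}


def test_additivity_of_adjacent_ranges(dataset, ranks):
    rng = np.random.default_rng(23)
    for _ in range(25):
        a = int(rng.integers(1, 90))
        b = int(rng.integers(a, 95))
        c = int(rng.integers(b + 1, 101))
        probe = ranks.probe_set_ids[rng.integers(ranks.n_probes)]
        left = esort(dataset.compendium, ranks, SortQuery(probe, "B cell", a, b))
        right = esort(dataset.compendium, ranks,
                      SortQuery(probe, "B cell", b + 1, c))
        whole = esort(dataset.compendium, ranks, SortQuery(probe, "B cell", a, c))
        assert hit_ids(left) | hit_ids(right) == hit_ids(whole)
        assert hit_ids(left) & hit_ids(right) == set()


def test_series_view_partitions_hits(dataset, ranks):
    query = SortQuery("PLS00001_at", "PMN/neutrophil", 88, 98)
    result = esort(dataset.compendium, ranks, query)
    assert result.n_hits > 0
    from_series = [s for ids, _ in result.series_view.values() for s in ids]
    assert sorted(from_series) == sorted(hit_ids(result))
    for series_id, (ids, n_in_series) in result.series_view.items():
        assert len(ids) <= n_in_series
        assert all(
            dataset.compendium.samples.set_index("sample_id")
            .loc[i, "series_id"] == series_id for i in ids)


def test_report_modes(dataset, ranks):
    query = SortQuery("MRK00001_at", "B cell", 90, 100)
    result = esort(dataset.compendium, ranks, query)
    sample_table = esort_report(result, mode="sample")
    assert len(sample_table) == result.n_hits
    assert list(sample_table.columns) == ["sample_id", "series_id", "title",
                                          "characteristics", "signal",
                                          "rank_score"]
    series_table = esort_report(result, mode="series")
    assert series_table["n_hits"].sum() == result.n_hits
    assert len(series_table) == len(result.series_view)
    with pytest.raises(ValueError, match="mode"):
        esort_report(result, mode="bogus")


def test_empty_result_report_is_header_only(dataset, ranks):
    scores = ranks.scores.loc["MRK00004_at",
                              dataset.compendium.samples_in_group("NK")]
    missing = next(s for s in range(30, 80) if (scores != s).all())
    result = esort(dataset.compendium, ranks,
                   SortQuery("MRK00004_at", "NK", missing, missing))
    table = esort_report(result, mode="sample")
    assert len(table) == 0 and "sample_id" in table.columns


def test_query_validation(dataset, ranks):
    with pytest.raises(ValueError, match="inverted"):
        SortQuery("MRK00001_at", "B cell", 50, 40)
    with pytest.raises(ValueError, match="unknown cell group"):
        esort(dataset.compendium, ranks,
              SortQuery("MRK00001_at", "Mast cell", 1, 100))
    with pytest.raises(KeyError):
        esort(dataset.compendium, ranks,
              SortQuery("missing_at", "B cell", 1, 100))
    with pytest.raises(ValueError, match="n_bins"):
        esort(dataset.compendium, ranks,
              SortQuery("MRK00001_at", "B cell", 1, 200))
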