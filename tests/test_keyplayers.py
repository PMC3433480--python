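"""Key-player selection, rankings and correlations on the published
85-compound centrality table and on random tables."""

import numpy as np
import pandas as pd
import pytest

from netpharm.keyplayers import (
    degree_betweenness_r2,
    dual_threshold_select,
    herb_attribution,
    rank_by,
    rank_compare,
    topk_intersection,
)


def _random_table(rng, n=30):
    return pd.DataFrame({
        "compound_id": [f"c{i}" for i in range(n)],
        "degree": rng.integers(1, 25, size=n),
        "betweenness": np.round(rng.uniform(0, 500, size=n), 4),
    })


def test_published_table_hub_counts(table5):
    assert (table5["degree"] >= 8).sum() == 43
    sel = dual_threshold_select(table5, 8, 48.05)
    assert len(sel) == 40


def test_published_table_top20_overlap(table5):
    inter = topk_intersection(table5, 20)
    assert inter.size == 18


def test_published_table_degree_betweenness_correlation(table5):
    assert degree_betweenness_r2(table5) == pytest.approx(0.77, abs=0.05)


def test_zero_thresholds_select_everything(table5):
    assert len(dual_threshold_select(table5, 0, 0)) == 85


def test_selection_antitone_in_both_thresholds(table5, rng):
    for _ in range(20):
        d1, d2 = sorted(rng.uniform(0, 30, 2))
        b1, b2 = sorted(rng.uniform(0, 600, 2))
        loose = dual_threshold_select(table5, d1, b1)
        strict = dual_threshold_select(table5, d2, b2)
        assert set(strict["compound_id"]) <= set(loose["compound_id"])


def test_topk_full_table_is_identity(table5):
    inter = topk_intersection(table5, len(table5))
    assert inter.size == len(table5)


def test_topk_matches_sort_and_intersect_oracle(rng):
    for _ in range(20):
        t = _random_table(rng)
        k = int(rng.integers(1, len(t)))
        got = topk_intersection(t, k)
        key_deg = sorted(
            t.itertuples(), key=lambda r: (-r.degree, -r.betweenness,
                                           r.compound_id))[:k]
        key_btw = sorted(
            t.itertuples(), key=lambda r: (-r.betweenness, -r.degree,
                                           r.compound_id))[:k]
        brute = {r.compound_id for r in key_deg} & \
            {r.compound_id for r in key_btw}
        assert got.members == brute
        assert got.size <= k


def test_identical_orderings_give_full_intersection():
    t = pd.DataFrame({"compound_id": list("abcde"),
                      "degree": [5, 4, 3, 2, 1],
                      "betweenness": [50, 40, 30, 20, 10.0]})
    assert topk_intersection(t, 3).size == 3


def test_rank_by_is_deterministic_under_ties():
    t = pd.DataFrame({"compound_id": ["b", "a", "c"],
                      "degree": [5, 5, 5],
                      "betweenness": [1.0, 1.0, 2.0]})
    assert list(rank_by(t, "degree")["compound_id"]) == ["c", "a", "b"]


def test_r2_exactly_one_for_collinear_table():
    t = pd.DataFrame({"compound_id": list("abcd"),
                      "degree": [1, 2, 3, 4],
                      "betweenness": [2.0, 4.0, 6.0, 8.0]})
    assert degree_betweenness_r2(t) == pytest.approx(1.0)


def test_r2_matches_textbook_covariance_formula(rng):
    t = _random_table(rng)
    d = t["degree"].astype(float)
    b = t["betweenness"]
    cov = ((d - d.mean()) * (b - b.mean())).mean()
    r2 = cov**2 / (d.var(ddof=0) * b.var(ddof=0))
    assert degree_betweenness_r2(t) == pytest.approx(r2)


def test_r2_invariant_under_affine_rescaling(table5):
    t = table5.copy()
    t["betweenness"] = 3.5 * t["betweenness"] + 11.0
    assert degree_betweenness_r2(t) == pytest.approx(
        degree_betweenness_r2(table5))


def test_r2_undefined_for_constant_degree():
    t = pd.DataFrame({"compound_id": list("abc"), "degree": [3, 3, 3],
                      "betweenness": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="constant"):
        degree_betweenness_r2(t)


def test_herb_attribution_counts_multi_herb_compounds_per_herb(tiny_library):
    counts = herb_attribution(["A1", "A2", "A3"], tiny_library)
    assert counts == {"H1": 2, "H2": 2}


def test_herb_attribution_empty_selection_all_zero(tiny_library):
    assert herb_attribution([], tiny_library) == {"H1": 0, "H2": 0}


def test_herb_attribution_unknown_compound_raises(tiny_library):
    with pytest.raises(KeyError):
        herb_attribution(["ZZ"], tiny_library)


def test_herb_attribution_matches_membership_scan(bundle, rng):
    lib = bundle.library
    selected = list(rng.choice(sorted(lib.compounds), size=25, replace=False))
    counts = herb_attribution(selected, lib)
    for herb, c in counts.items():
        assert c == sum(1 for cid in selected if herb in lib[cid].herbs)


def test_metabolite_outranks_parent_in_published_table(table5):
    # ginsenoside Rb1 (M235) vs its intestinal metabolite compound K (MCK)
    verdicts = rank_compare(table5, [("M235", ["MCK"])])
    assert verdicts[("M235", "MCK")] is True


def test_compound_never_outranks_itself(table5):
    verdicts = rank_compare(table5, [("M13", ["M13"])])
    assert verdicts[("M13", "M13")] is False


def test_rank_compare_matches_tuple_oracle(rng):
    t = _random_table(rng)
    idx = t.set_index("compound_id")
    parents = list(rng.choice(t["compound_id"], size=5, replace=False))
    mets = list(rng.choice(t["compound_id"], size=5, replace=False))
    verdicts = rank_compare(t, [(p, [m]) for p, m in zip(parents, mets)])
    for (p, m), v in verdicts.items():
        expected = (idx.loc[m, "betweenness"], idx.loc[m, "degree"]) > \
            (idx.loc[p, "betweenness"], idx.loc[p, "degree"])
        assert v == expected


def test_rank_compare_missing_id_raises(table5):
    with pytest.raises(KeyError, match="M999"):
        rank_compare(table5, [("M13", ["M999"])])
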