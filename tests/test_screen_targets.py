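"""Hit filtering, disease-relevance partition and docking validation."""

import math

import pytest

from netpharm.library import TargetRecord
from netpharm.screen_targets import (
    InteractionRecord,
    ScreenError,
    annotate_disease_relevance,
    docking_validate,
    filter_hits,
    run_cascade,
)


def _hit(c, t, fit, rank, energy=None):
    return InteractionRecord(c, t, fit, rank, energy)


def _annotations(flags):
    return {
        t: TargetRecord(target_id=t, cvd_related=f,
                        diseases=frozenset({"x"}) if f else frozenset())
        for t, f in flags.items()
    }


def test_fit_boundary_inclusive_and_rank_boundary_inclusive():
    hits = [_hit("c", "t1", 3.00, 300), _hit("c", "t2", 2.999, 1),
            _hit("c", "t3", 5.0, 301)]
    res = filter_hits(hits, allowed_targets={"t1", "t2", "t3"})
    assert [h.target_id for h in res.interactions] == ["t1"]


def test_negative_fit_score_rejected():
    with pytest.raises(ScreenError, match="negative fit"):
        _hit("c", "t", -0.1, 1)


def test_compounds_with_emptied_hit_lists_reported():
    hits = [_hit("a", "t1", 4.0, 1), _hit("b", "t1", 1.0, 1)]
    res = filter_hits(hits, allowed_targets={"t1"})
    assert res.compounds_without_hits == frozenset({"b"})


def test_filter_matches_brute_force_triple_predicate(rng):
    targets = [f"t{i}" for i in range(30)]
    allowed = set(targets[:20])
    hits = []
    for c in range(15):
        scored = sorted(
            ((float(rng.uniform(0, 6)), targets[int(rng.integers(0, 30))])
             for _ in range(int(rng.integers(1, 25)))),
            key=lambda x: -x[0])
        hits += [_hit(f"c{c}", t, f, r + 1)
                 for r, (f, t) in enumerate(scored)]
    res = filter_hits(hits, min_fit=3.0, max_rank=10, allowed_targets=allowed)
    brute = [h for h in hits
             if h.fit_score >= 3.0 and h.rank <= 10 and h.target_id in allowed]
    assert res.interactions == brute
    assert res.candidate_targets == {h.target_id for h in brute}


def test_relevance_partition_matches_flag_scan():
    ann = _annotations({"t1": True, "t2": False, "t3": True})
    part = annotate_disease_relevance({"t1", "t2", "t3"}, ann)
    assert part.relevant == frozenset({"t1", "t3"})
    assert part.not_relevant == frozenset({"t2"})


def test_all_flags_false_gives_empty_relevant_set():
    ann = _annotations({"t1": False, "t2": False})
    part = annotate_disease_relevance({"t1", "t2"}, ann)
    assert part.relevant == frozenset()


def test_unannotated_target_error_lists_missing_ids():
    with pytest.raises(ScreenError, match="t9"):
        annotate_disease_relevance({"t9"}, _annotations({"t1": True}))


def test_compounds_with_only_irrelevant_targets_flagged():
    ann = _annotations({"t1": True, "t2": False})
    hits = [_hit("a", "t1", 4, 1), _hit("b", "t2", 4, 1)]
    part = annotate_disease_relevance({"t1", "t2"}, ann, interactions=hits)
    assert part.compounds_without_relevant_target == frozenset({"b"})


def test_docking_boundary_inclusive_and_eliminations_reported():
    inter = [_hit("a", "t1", 4, 1), _hit("a", "t2", 4, 2),
             _hit("b", "t2", 4, 1)]
    energies = {("a", "t1"): -5.0, ("a", "t2"): 29.75, ("b", "t2"): -4.99}
    res = docking_validate(inter, energies)
    assert [(r.compound_id, r.target_id) for r in res.interactions] == [("a", "t1")]
    assert res.eliminated_compounds == frozenset({"b"})
    assert res.eliminated_targets == frozenset({"t2"})


def test_docking_with_infinite_cutoff_is_identity():
    inter = [_hit("a", "t1", 4, 1, 10.0), _hit("b", "t2", 4, 1, -2.0)]
    res = docking_validate(inter, max_energy=math.inf)
    assert [(r.compound_id, r.target_id) for r in res.interactions] == \
        [("a", "t1"), ("b", "t2")]


def test_missing_energy_names_the_pair():
    with pytest.raises(ScreenError, match=r"\(a, t1\)"):
        docking_validate([_hit("a", "t1", 4, 1)], {})


def test_cascade_monotone_and_report_self_consistent(bundle):
    docking, report = run_cascade(
        bundle.hits, bundle.targets, bundle.energies,
        allowed_targets=set(bundle.targets))
    assert report.n_candidate_interactions <= report.n_raw_hits
    assert report.n_relevant_interactions <= report.n_candidate_interactions
    assert report.n_potential_interactions <= report.n_relevant_interactions
    # recomputed counts equal the report
    assert report.n_potential_interactions == len(docking.interactions)
    assert report.n_potential_targets == len(docking.potential_targets)
    assert report.n_potential_compounds == len(
        {r.compound_id for r in docking.interactions})
    # potential interactions are a subset of the raw pairs
    raw_pairs = {(h.compound_id, h.target_id) for h in bundle.hits}
    assert {(r.compound_id, r.target_id)
            for r in docking.interactions} <= raw_pairs
    # eliminated-compound lists are disjoint across stages
    stages = [report.eliminated_no_hit,
              report.eliminated_no_relevant_target,
              report.eliminated_by_docking]
    assert len(stages[0] | stages[1] | stages[2]) == sum(map(len, stages))


@pytest.mark.parametrize("cutoff_pair", [(-6.0, -5.0), (-5.0, -3.0)])
def test_docking_filter_antitone_in_cutoff(bundle, cutoff_pair):
    strict, loose = cutoff_pair
    inter = [h for h in bundle.hits
             if (h.compound_id, h.target_id) in bundle.energies]
    a = docking_validate(inter, bundle.energies, strict)
    b = docking_validate(inter, bundle.energies, loose)
    assert {(r.compound_id, r.target_id) for r in a.interactions} <= \
        {(r.compound_id, r.target_id) for r in b.interactions}
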