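import itertools

import numpy as np
import pytest

from pvsignal import (
    DuplicateGroup,
    Gender,
    MatchStage,
    PartialDate,
    ReportDatabase,
    SourceType,
    default_stage_ladder,
    find_duplicates,
    remove_duplicates,
)
from pvsignal.dedup import _stage_key
from pvsignal.synthetic import SimulationConfig, simulate_database

from conftest import make_report

STAGE_GA_DE = MatchStage(
    "gender+age+drugs+events",
    frozenset({"gender", "age"}),
    2.0,
    frozenset({"drug_set", "event_set"}),
)


def clone(r, rid, **overrides):
    import dataclasses

    return dataclasses.replace(r, report_id=rid, **overrides)


def test_identical_reports_form_one_group():
    a = make_report("a", drugs=["d"], events=["x"])
    db = ReportDatabase([a, clone(a, "b")])
    groups = find_duplicates(db, [STAGE_GA_DE])
    assert len(groups) == 1
    assert groups[0].member_ids == {"a", "b"}


def test_gender_mismatch_blocks_grouping():
    a = make_report("a", gender=Gender.F, drugs=["d"], events=["x"])
    b = clone(a, "b", gender=Gender.M)
    assert find_duplicates(ReportDatabase([a, b]), [STAGE_GA_DE]) == []


def test_unknown_gender_never_matches():
    a = make_report("a", gender=Gender.UNKNOWN, drugs=["d"], events=["x"])
    b = clone(a, "b")
    assert find_duplicates(ReportDatabase([a, b]), [STAGE_GA_DE]) == []


def brute_force_groups(db, stage):
    """Independent oracle: explicit pairwise matching + connected components."""

    def pair_matches(r1, r2):
        k1, k2 = _stage_key(r1, stage), _stage_key(r2, stage)
        if k1 is None or k2 is None or k1 != k2:
            return False
        if "age" in stage.required_demographic_fields:
            return abs(r1.age_years - r2.age_years) <= stage.age_tolerance_years
        return True

    ids = db.report_ids
    adj = {i: set() for i in ids}
    for i, j in itertools.combinations(ids, 2):
        if pair_matches(db[i], db[j]):
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in ids:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        if len(comp) >= 2:
            comps.append(frozenset(comp))
    return set(comps)


def test_age_tolerance_chains_nearby_ages_only():
    a = make_report("a", age=40, drugs=["d"], events=["x"])
    db = ReportDatabase([a, clone(a, "b", age_years=41.0), clone(a, "c", age_years=45.0)])
    groups = find_duplicates(db, [STAGE_GA_DE])
    assert {g.member_ids for g in groups} == {frozenset({"a", "b"})}
    assert brute_force_groups(db, STAGE_GA_DE) == {frozenset({"a", "b"})}


def test_groups_match_brute_force_on_random_databases():
    rng = np.random.default_rng(123)
    for _ in range(10):
        reports = []
        for i in range(30):
            reports.append(
                make_report(
                    f"r{i}",
                    gender=Gender.F if rng.random() < 0.5 else Gender.M,
                    age=float(rng.integers(38, 46)),
                    drugs=[("d", PartialDate(2010, 1, 1))] if rng.random() < 0.8 else [],
                    events=[("x", PartialDate(2010, 2, 1))] if rng.random() < 0.8 else [],
                )
            )
        db = ReportDatabase(reports)
        found = {g.member_ids for g in find_duplicates(db, [STAGE_GA_DE])}
        assert found == brute_force_groups(db, STAGE_GA_DE)


def test_death_date_compared_only_when_present_in_both():
    stage = MatchStage(
        "with death",
        frozenset({"gender", "age", "death_date"}),
        1.0,
        frozenset({"drug_set", "event_set"}),
    )
    base = make_report("a", drugs=["d"], events=["x"])
    both_none = ReportDatabase([base, clone(base, "b")])
    assert len(find_duplicates(both_none, [stage])) == 1
    one_dated = ReportDatabase(
        [base, clone(base, "b", death_date=PartialDate(2011, 3, 1))]
    )
    assert find_duplicates(one_dated, [stage]) == []


def test_missing_required_record_field_blocks_match():
    stage = MatchStage(
        "needs manufacturer",
        frozenset({"gender", "age"}),
        1.0,
        frozenset({"manufacturer", "drug_set", "event_set"}),
    )
    a = make_report("a", drugs=["d"], events=["x"], manufacturer=None)
    db = ReportDatabase([a, clone(a, "b")])
    assert find_duplicates(db, [stage]) == []


def test_earlier_stage_claims_reports_first():
    strict = MatchStage(
        "strict",
        frozenset({"gender", "age"}),
        0.0,
        frozenset({"drug_set", "event_set"}),
    )
    a = make_report("a", age=40, drugs=["d"], events=["x"])
    db = ReportDatabase([a, clone(a, "b"), clone(a, "c", age_years=41.0)])
    groups = find_duplicates(db, [strict, STAGE_GA_DE])
    # strict stage claims a+b; c then has no ungrouped partner left
    assert len(groups) == 1
    assert groups[0].stage_name == "strict"
    assert groups[0].member_ids == {"a", "b"}


def test_source_restriction_controls_stage_eligibility():
    stage = MatchStage(
        "spontaneous only",
        frozenset({"gender", "age"}),
        1.0,
        frozenset({"drug_set", "event_set"}),
        frozenset({SourceType.SPONTANEOUS}),
    )
    a = make_report("a", drugs=["d"], events=["x"], source=SourceType.LITERATURE)
    db = ReportDatabase([a, clone(a, "b")])
    assert find_duplicates(db, [stage]) == []


def test_remove_no_groups_is_identity():
    db = ReportDatabase([make_report(f"r{i}") for i in range(5)])
    assert remove_duplicates(db, []) == db


def test_remove_keeps_one_representative_per_group():
    db = ReportDatabase([make_report(f"r{i}", drugs=["d"], events=["x"]) for i in range(10)])
    group = DuplicateGroup(frozenset({"r0", "r1", "r2"}), "s", "r0")
    out = remove_duplicates(db, [group], keep_rule="lexicographic_id")
    assert len(out) == 8
    assert "r0" in out and "r1" not in out and "r2" not in out


def test_latest_receipt_keep_rule_prefers_newest_report():
    a = make_report("a", drugs=["d"], events=["x"], receipt_date=PartialDate(2010, 1, 1))
    b = clone(a, "b", receipt_date=PartialDate(2012, 1, 1))
    db = ReportDatabase([a, b])
    out = remove_duplicates(
        db, [DuplicateGroup(frozenset({"a", "b"}), "s", "b")], keep_rule="latest_receipt"
    )
    assert out.report_ids == ["b"]


def test_overlapping_groups_rejected():
    db = ReportDatabase([make_report(f"r{i}", drugs=["d"], events=["x"]) for i in range(4)])
    g1 = DuplicateGroup(frozenset({"r0", "r1"}), "s", "r0")
    g2 = DuplicateGroup(frozenset({"r1", "r2"}), "s", "r1")
    with pytest.raises(ValueError):
        remove_duplicates(db, [g1, g2])


def test_find_and_remove_is_idempotent_on_generator_output():
    db, _ = simulate_database(
        SimulationConfig(n_reports=2000, seed=5, duplicate_fraction=0.1)
    )
    stages = default_stage_ladder()
    once = remove_duplicates(db, find_duplicates(db, stages))
    twice = remove_duplicates(once, find_duplicates(once, stages))
    assert once == twice


def test_larger_age_tolerance_never_groups_fewer_reports():
    db, _ = simulate_database(
        SimulationConfig(n_reports=1500, seed=9, duplicate_fraction=0.08)
    )
    grouped_counts = []
    for tol in (0.0, 1.0, 2.0, 5.0):
        groups = find_duplicates(db, default_stage_ladder(age_tolerance_years=tol))
        grouped_counts.append(sum(len(g.member_ids) for g in groups))
    assert grouped_counts == sorted(grouped_counts)


def test_stage_requires_at_least_one_field():
    with pytest.raises(ValueError):
        MatchStage("empty", frozenset(), 1.0, frozenset())
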