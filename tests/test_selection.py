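"""Exclusion cascade, eligibility percentiles and greedy matching."""

import dataclasses

import pytest

import vkrpipe as v
from vkrpipe import (
    CascadeReport,
    apply_exclusion_cascade,
    match_pairs,
    select_cases,
    select_controls,
)
from conftest import CASE_KP, CASE_QOL, CLEAN_KP, CLEAN_QOL


class TestCascade:
    def test_one_knee_per_exclusion_reason(self, make_knee):
        cohort = [
            make_knee("P00001-R", kr_month=6),
            make_knee("P00002-R", months=(0,)),  # no follow-up at all
            make_knee("P00003-R", coverage=False),
            make_knee("P00004-R", missing_pro=(12,)),  # insufficient KOOS
            make_knee("P00005-R", klg=None),  # no baseline reading
        ] + [make_knee(f"P0001{i}-R") for i in range(5)]
        report = apply_exclusion_cascade(cohort)
        assert [s.n_removed for s in report.steps] == [1, 1, 1, 1, 1]
        assert report.final_n == 5
        assert report.removed["P00003-R"] == "no_continuous_coverage"

    def test_first_matching_step_wins(self, make_knee):
        # Fails coverage AND KLG; must be counted only at the coverage step.
        knee = make_knee("P00001-R", coverage=False, klg=None)
        report = apply_exclusion_cascade([knee])
        assert report.removed["P00001-R"] == "no_continuous_coverage"
        assert [s.n_removed for s in report.steps] == [0, 0, 1, 0, 0]

    def test_all_clean_cohort_removes_nothing(self, make_knee):
        report = apply_exclusion_cascade([make_knee(f"P0000{i}-R") for i in range(4)])
        assert all(s.n_removed == 0 for s in report.steps)
        assert report.final_n == 4

    def test_counts_always_reconcile(self, make_knee):
        cohort = [make_knee(f"P{i:05d}-R", coverage=i % 3 != 0) for i in range(30)]
        report = apply_exclusion_cascade(cohort)
        assert report.initial_n - sum(s.n_removed for s in report.steps) == report.final_n

    def test_from_counts_rejects_bad_arithmetic(self):
        report = CascadeReport.from_counts(100, [("a", 10), ("b", 5)])
        assert report.final_n == 85
        report.steps[1] = dataclasses.replace(report.steps[1], n_remaining=99)
        with pytest.raises(ValueError):
            report.validate()


def _planted_case(make_knee, knee_id, **kw):
    return make_knee(knee_id, kp=CASE_KP, qol=CASE_QOL, **kw)


def _clean_knee(make_knee, knee_id, level=0.0, **kw):
    kp = {m: s - level for m, s in CLEAN_KP.items()}
    qol = {m: s - level for m, s in CLEAN_QOL.items()}
    return make_knee(knee_id, kp=kp, qol=qol, **kw)


class TestSelectCases:
    def test_planted_cases_selected_exactly(self, make_knee):
        planted = [_planted_case(make_knee, f"P000{i:02d}-R") for i in range(2)]
        others = [
            _clean_knee(make_knee, f"P001{i:02d}-R", level=i * 0.1) for i in range(18)
        ]
        assert select_cases(planted + others) == sorted(k.knee_id for k in planted)

    def test_case_first_at_48_excluded(self, make_knee):
        kp = {0: 90, 12: 85, 24: 80, 36: 50, 48: 45, 60: 42, 72: 40}
        qol = {0: 80, 12: 75, 24: 65, 36: 40, 48: 36, 60: 33, 72: 30}
        early = make_knee("P00001-R", kp=kp, qol=qol)
        others = [_clean_knee(make_knee, f"P001{i:02d}-R", level=i * 0.1) for i in range(18)]
        assert select_cases([early] + others) == []

    def test_unreadable_mri_excluded(self, make_knee):
        planted = _planted_case(make_knee, "P00001-R", unreadable=(36,))
        others = [_clean_knee(make_knee, f"P001{i:02d}-R", level=i * 0.1) for i in range(18)]
        assert select_cases([planted] + others) == []


class TestSelectControls:
    def test_exact_percentile_count_on_distinct_scores(self, make_knee):
        cohort = [
            _clean_knee(make_knee, f"P{i:05d}-R", level=i * 0.01) for i in range(1000)
        ]
        controls = select_controls(cohort, cases=[])
        assert len(controls) == 200
        # The 200 kept must be the 200 highest-score (lowest-risk) knees.
        assert controls == sorted(f"P{i:05d}-R" for i in range(200))

    def test_contralateral_case_blocks_control(self, make_knee):
        case_knee = _planted_case(make_knee, "P00001-R")
        sibling = _clean_knee(make_knee, "P00001-L")
        others = [_clean_knee(make_knee, f"P001{i:02d}-R", level=5 + i) for i in range(8)]
        cases = [case_knee.knee_id]
        controls = select_controls([case_knee, sibling] + others, cases)
        assert "P00001-L" not in controls

    def test_contralateral_surgical_kr_blocks_control(self, make_knee):
        sibling = _clean_knee(make_knee, "P00001-L")
        kr_knee = make_knee("P00001-R", kr_month=48)
        others = [_clean_knee(make_knee, f"P001{i:02d}-R", level=5 + i) for i in range(8)]
        controls = select_controls([sibling, kr_knee] + others, cases=[])
        assert "P00001-L" not in controls

    def test_perfect_score_knee_with_clean_contralateral_included(self, make_knee):
        perfect = make_knee(
            "P00001-R", kp={m: 100.0 for m in v.MONTHS}, qol={m: 100.0 for m in v.MONTHS}
        )
        sibling = _clean_knee(make_knee, "P00001-L", level=3)
        others = [_clean_knee(make_knee, f"P001{i:02d}-R", level=5 + i) for i in range(8)]
        controls = select_controls([perfect, sibling] + others, cases=[])
        assert "P00001-R" in controls


class TestMatchPairs:
    def test_in_caliper_match(self, make_knee):
        case = make_knee("P00001-R", age=60)
        ctrl = make_knee("P00002-R", age=64)
        pairs, unmatched = match_pairs([case], [ctrl])
        assert len(pairs) == 1 and not unmatched
        assert pairs[0].age_gap == 4

    def test_out_of_caliper_unmatched(self, make_knee):
        pairs, unmatched = match_pairs(
            [make_knee("P00001-R", age=60)], [make_knee("P00002-R", age=66)]
        )
        assert not pairs and unmatched == ["P00001-R"]

    def test_greedy_order_consumes_nearest_control(self, make_knee):
        cases = [make_knee("P00001-R", age=60), make_knee("P00002-R", age=62)]
        pool = [make_knee("P00011-R", age=61), make_knee("P00012-R", age=70)]
        pairs, unmatched = match_pairs(cases, pool)
        assert [(p.case_knee_id, p.control_knee_id) for p in pairs] == [
            ("P00001-R", "P00011-R")
        ]
        assert unmatched == ["P00002-R"]

    def test_stratum_mismatch_blocks_match(self, make_knee):
        case = make_knee("P00001-R", age=60, klg=3, jsn=(2, 0))
        for ctrl_kw in ({"klg": 2}, {"sex": "M"}, {"jsn": (0, 2)}):
            ctrl = make_knee("P00002-R", age=60, **{"klg": 3, "jsn": (2, 0), **ctrl_kw})
            pairs, unmatched = match_pairs([case], [ctrl])
            assert unmatched == ["P00001-R"], ctrl_kw

    def test_klg_0_and_1_share_a_stratum(self, make_knee):
        case = make_knee("P00001-R", age=60, klg=0, jsn=(0, 0))
        ctrl = make_knee("P00002-R", age=60, klg=1, jsn=(0, 0))
        pairs, _ = match_pairs([case], [ctrl])
        assert len(pairs) == 1
        assert pairs[0].klg_stratum == "0-1" and pairs[0].jsn_dominant == "none"

    def test_deterministic_under_seed(self, make_knee):
        cases = [make_knee(f"P000{i:02d}-R", age=60) for i in range(5)]
        pool = [make_knee(f"P001{i:02d}-R", age=60) for i in range(10)]
        a = match_pairs(cases, pool, seed=42)
        b = match_pairs(cases, pool, seed=42)
        assert a == b

    def test_every_case_with_candidate_is_matched(self, make_knee):
        cases = [make_knee(f"P000{i:02d}-R", age=55 + i) for i in range(10)]
        pool = [make_knee(f"P001{i:02d}-R", age=55 + i) for i in range(10)]
        pairs, unmatched = match_pairs(cases, pool)
        assert len(pairs) == 10 and not unmatched
        assert len({p.control_knee_id for p in pairs}) == 10

    def test_invalid_caliper_rejected(self, make_knee):
        with pytest.raises(ValueError):
            match_pairs([make_knee("P00001-R")], [make_knee("P00002-R")], age_caliper=0)

    def test_overlapping_pools_rejected(self, make_knee):
        k = make_knee("P00001-R")
        with pytest.raises(ValueError):
            match_pairs([k], [k])


class TestRadiographicTypes:
    def test_klg_stratum_mapping(self):
        assert [v.cohort.klg_stratum(g) for g in range(5)] == ["0-1", "0-1", "2", "3", "4"]

    @pytest.mark.parametrize(
        "jm,jl,expected",
        [(0, 0, "none"), (2, 2, "both"), (2, 1, "medial"), (1, 3, "lateral")],
    )
    def test_jsn_dominant_rules(self, jm, jl, expected):
        assert v.cohort.jsn_dominant(jm, jl) == expected

    def test_inconsistent_stratum_rejected(self):
        with pytest.raises(ValueError):
            v.RadiographicBaseline(
                klg=2, klg_stratum="3", jsn_medial=1, jsn_lateral=0, jsn_dominant="medial"
            )
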