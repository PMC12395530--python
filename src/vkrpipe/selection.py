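"""Exclusion cascade, case/control eligibility and 1:1 stratified matching.

The study design removes knees in a fixed order (surgical KR before 12
months, no follow-up, no continuous health coverage, insufficient KOOS
data, no baseline radiographic reading), selects cases as knees first
reaching vKR status at the target visit with complete MRI coverage and
a composite score in the highest-risk fraction of the eligible
population, selects controls from the lowest-risk fraction with a
clean contralateral knee, and matches cases 1:1 to controls within
exact strata (sex, KLG stratum, JSN-dominant compartment) under an age
caliper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .classifier import VkrModelParams, composite_score, first_case_month
from .cohort import KneeSeries

# Machine-readable cascade step labels, in application order.
STEP_KR_BEFORE_12M = "kr_before_12m"
STEP_NO_12M_FOLLOWUP = "no_12m_followup"
STEP_NO_COVERAGE = "no_continuous_coverage"
STEP_INSUFFICIENT_KOOS = "insufficient_koos"
STEP_NO_BASELINE_KLG = "no_baseline_klg"


@dataclass(frozen=True)
class CascadeStep:
    label: str
    n_removed: int
    n_remaining: int


@dataclass
class CascadeReport:
    """Accounting of the exclusion cascade.

    ``steps`` hold the per-step removals in order; counts always
    reconcile (initial n minus total removed equals the final n).
    ``removed`` maps each excluded knee id to the step that removed it.
    """

    initial_n: int
    steps: list[CascadeStep] = field(default_factory=list)
    eligible: list[KneeSeries] = field(default_factory=list)
    removed: dict[str, str] = field(default_factory=dict)

    @property
    def final_n(self) -> int:
        return self.steps[-1].n_remaining if self.steps else self.initial_n

    def validate(self) -> None:
        n = self.initial_n
        for step in self.steps:
            if step.n_removed < 0:
                raise ValueError(f"negative removal at {step.label}")
            n -= step.n_removed
            if step.n_remaining != n:
                raise ValueError(f"counts do not reconcile at {step.label}")
        if self.eligible and len(self.eligible) != self.final_n:
            raise ValueError("eligible set size does not match final count")

    @classmethod
    def from_counts(
        cls, initial_n: int, removals: Sequence[tuple[str, int]]
    ) -> "CascadeReport":
        """Fold printed (label, n_removed) rows into a reconciled report."""
        report = cls(initial_n=initial_n)
        n = initial_n
        for label, removed in removals:
            n -= removed
            report.steps.append(CascadeStep(label, removed, n))
        report.validate()
        return report


def _has_followup(knee: KneeSeries) -> bool:
    return any(v.present and v.visit_month >= 12 for v in knee.pro_visits) or any(
        v.readable and v.visit_month >= 12 for v in knee.cartilage_visits
    )


def _has_koos(knee: KneeSeries, month: int) -> bool:
    v = knee.pro_at(month)
    return v is not None and v.present


def apply_exclusion_cascade(
    cohort: Sequence[KneeSeries], target_month: int = 60
) -> CascadeReport:
    """Apply the five exclusion steps in order, first match wins."""
    checks: list[tuple[str, Callable[[KneeSeries], bool]]] = [
        (
            STEP_KR_BEFORE_12M,
            lambda k: k.surgical_kr_month is not None and k.surgical_kr_month < 12,
        ),
        (STEP_NO_12M_FOLLOWUP, lambda k: not _has_followup(k)),
        (STEP_NO_COVERAGE, lambda k: not k.continuous_coverage),
        (
            STEP_INSUFFICIENT_KOOS,
            lambda k: not (_has_koos(k, 0) and _has_koos(k, 12)),
        ),
        (STEP_NO_BASELINE_KLG, lambda k: k.radiographic is None),
    ]
    report = CascadeReport(initial_n=len(cohort))
    remaining = list(cohort)
    for label, bad in checks:
        kept: list[KneeSeries] = []
        removed = 0
        for knee in remaining:
            if bad(knee):
                removed += 1
                report.removed[knee.knee_id] = label
            else:
                kept.append(knee)
        remaining = kept
        report.steps.append(CascadeStep(label, removed, len(remaining)))
    report.eligible = remaining
    report.validate()
    return report


def _score_at(knee: KneeSeries, t0: int, params: VkrModelParams) -> Optional[float]:
    v0, vm1 = knee.pro_at(t0), knee.pro_at(t0 - 12)
    if v0 is None or not v0.present or vm1 is None or not vm1.present:
        return None
    _, score = composite_score(
        v0.koos_pain, vm1.koos_pain, v0.koos_qol, vm1.koos_qol, params
    )
    return score


def population_scores(
    eligible: Sequence[KneeSeries],
    params: VkrModelParams = VkrModelParams(),
    target_month: int = 60,
) -> dict[str, float]:
    """Composite scores at the t0 cross-section (target_month - 12).

    The case/control percentiles are computed over this cross-section
    of the eligible population; knees without the two visits needed
    for a score are omitted.
    """
    t0 = target_month - 12
    scores: dict[str, float] = {}
    for knee in eligible:
        s = _score_at(knee, t0, params)
        if s is not None:
            scores[knee.knee_id] = s
    return scores


def select_cases(
    eligible: Sequence[KneeSeries],
    params: VkrModelParams = VkrModelParams(),
    target_month: int = 60,
    require_mri_through: int = 48,
) -> list[str]:
    """Knee ids first reaching vKR case status exactly at the target month.

    Requires membership in the highest-risk ``case_top_fraction`` of
    the eligible population's composite scores at t0 (lower score =
    higher risk) and readable MRI at every annual visit from baseline
    through ``require_mri_through``.
    """
    scores = population_scores(eligible, params, target_month)
    if not scores:
        return []
    srt = np.sort(np.fromiter(scores.values(), dtype=float))
    k = int(np.floor(params.case_top_fraction * srt.size))
    if k <= 0:
        return []
    cut = float(srt[k - 1])  # inclusive: the k lowest (highest-risk) scores
    mri_months = [m for m in range(0, require_mri_through + 1, 12)]
    out: list[str] = []
    for knee in eligible:
        s = scores.get(knee.knee_id)
        if s is None or s > cut:
            continue
        if first_case_month(knee, params) != target_month:
            continue
        if any(
            (cv := knee.cart_at(m)) is None or not cv.readable for m in mri_months
        ):
            continue
        out.append(knee.knee_id)
    return sorted(out)


def select_controls(
    eligible: Sequence[KneeSeries],
    cases: Sequence[str],
    params: VkrModelParams = VkrModelParams(),
    target_month: int = 60,
) -> list[str]:
    """Knee ids in the lowest-risk fraction, with a clean contralateral.

    Keeps knees whose composite score at t0 lies at or above the
    empirical (1 - control_bottom_fraction) percentile, excluding case
    knees and any knee whose contralateral is a vKR case or had a
    surgical KR by the target month.
    """
    scores = population_scores(eligible, params, target_month)
    if not scores:
        return []
    srt = np.sort(np.fromiter(scores.values(), dtype=float))
    n = srt.size
    k = int(np.floor(params.control_bottom_fraction * n))
    if k <= 0:
        return []
    threshold = float(srt[n - k])
    case_set = set(cases)
    by_participant: dict[str, list[KneeSeries]] = {}
    for knee in eligible:
        by_participant.setdefault(knee.participant_id, []).append(knee)
    # Contralateral case status must consider all knees of the cohort we
    # can see; a contralateral knee absent from `eligible` cannot veto.
    out: list[str] = []
    for knee in eligible:
        s = scores.get(knee.knee_id)
        if s is None or s < threshold or knee.knee_id in case_set:
            continue
        contra_bad = False
        for other in by_participant.get(knee.participant_id, []):
            if other.knee_id == knee.knee_id:
                continue
            if other.knee_id in case_set:
                contra_bad = True
            elif (
                other.surgical_kr_month is not None
                and other.surgical_kr_month <= target_month
            ):
                contra_bad = True
            elif first_case_month(other, params) is not None and first_case_month(
                other, params
            ) <= target_month:
                contra_bad = True
        if not contra_bad:
            out.append(knee.knee_id)
    return sorted(out)


@dataclass(frozen=True)
class MatchedPair:
    """One case knee bound to one control knee with its matching stratum."""

    case_knee_id: str
    control_knee_id: str
    sex: str
    case_age: float
    control_age: float
    klg_stratum: str
    jsn_dominant: str
    age_gap: float

    def __post_init__(self) -> None:
        if abs(self.case_age - self.control_age) != self.age_gap:
            raise ValueError("age_gap inconsistent with ages")


def match_pairs(
    cases: Sequence[KneeSeries],
    control_pool: Sequence[KneeSeries],
    age_caliper: float = 5.0,
    seed: int = 0,
) -> tuple[list[MatchedPair], list[str]]:
    """Greedy 1:1 matching without replacement.

    Cases are processed in ascending knee-id order; within exact strata
    (sex, KLG stratum, JSN-dominant compartment) the unused control
    minimizing the absolute age difference is taken, ties broken by a
    seeded uniform draw.  Cases with no in-caliper candidate are
    returned unmatched.
    """
    if age_caliper <= 0:
        raise ValueError("age_caliper must be > 0")
    case_ids = {k.knee_id for k in cases}
    if case_ids & {k.knee_id for k in control_pool}:
        raise ValueError("case and control pools must be disjoint")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 104])
    available = {k.knee_id: k for k in control_pool}
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for case in sorted(cases, key=lambda k: k.knee_id):
        if case.radiographic is None:
            unmatched.append(case.knee_id)
            continue
        stratum = (
            case.sex,
            case.radiographic.klg_stratum,
            case.radiographic.jsn_dominant,
        )
        candidates = [
            c
            for c in available.values()
            if c.radiographic is not None
            and (c.sex, c.radiographic.klg_stratum, c.radiographic.jsn_dominant)
            == stratum
            and abs(c.age_baseline - case.age_baseline) <= age_caliper
        ]
        if not candidates:
            unmatched.append(case.knee_id)
            continue
        best_gap = min(abs(c.age_baseline - case.age_baseline) for c in candidates)
        tied = sorted(
            (
                c.knee_id
                for c in candidates
                if abs(c.age_baseline - case.age_baseline) == best_gap
            )
        )
        chosen_id = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        chosen = available.pop(chosen_id)
        pairs.append(
            MatchedPair(
                case_knee_id=case.knee_id,
                control_knee_id=chosen.knee_id,
                sex=case.sex,
                case_age=case.age_baseline,
                control_age=chosen.age_baseline,
                klg_stratum=case.radiographic.klg_stratum,
                jsn_dominant=case.radiographic.jsn_dominant,
                age_gap=abs(chosen.age_baseline - case.age_baseline),
            )
        )
    _assert_valid_pairs(pairs, age_caliper)
    return pairs, unmatched


def _assert_valid_pairs(pairs: Sequence[MatchedPair], age_caliper: float) -> None:
    used = [p.control_knee_id for p in pairs]
    if len(used) != len(set(used)):
        raise AssertionError("a control was used twice")
    for p in pairs:
        if p.age_gap > age_caliper:
            raise AssertionError(f"pair {p.case_knee_id} violates the age caliper")
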