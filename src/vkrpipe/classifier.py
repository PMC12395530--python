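"""Virtual knee replacement (vKR) decision rule and threshold calibration.

The vKR endpoint labels a knee-year as a "virtual KR" case from
patient-reported outcomes alone: the knee's KOOS pain and KOOS quality
of life (QoL) at the current visit (t0), the prior visit (t-1), the
baseline visit, and the next visit (t+1).  The published rule has two
branches, split on whether current pain is worse (lower) than the
prior year's:

* pain not worse:  score = KP_t0 + 0.54 * max(QoL_t0, QoL_t-1)
* pain worse:      score = KP_t0 + 0.54 * max(QoL_t0, QoL_t-1)
                           - 1.06 * |KP_t-1 - KP_t0|

and three conditions, all of which must hold for case status:

1. score < 95.7 (a threshold calibrated to 90% specificity against
   knees that did not undergo surgical KR);
2. both KP_t0 and QoL_t0 strictly below their baseline values;
3. both KP_t+1 and QoL_t+1 less than or equal to their t0 values.

Case status is attributed to the *following* annual visit (t0 + 12
months).  A knee-year with any required visit missing, or with a
surgical KR on or before t0 + 12, is not evaluable and never a case.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import MONTHS, KneeSeries

PAIN_NOT_WORSE = "pain_not_worse"
PAIN_WORSE = "pain_worse"
MAINTAINED = "vKR+/+"
NOT_MAINTAINED = "vKR+/-"


class MissingVisitError(ValueError):
    """A visit required by the operation is absent."""


@dataclass(frozen=True)
class VkrModelParams:
    """Published decision-rule constants plus selection settings."""

    qol_weight: float = 0.54
    worsening_weight: float = 1.06
    threshold: float = 95.7
    specificity: float = 0.90
    case_top_fraction: float = 0.10
    control_bottom_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.qol_weight <= 0 or self.worsening_weight <= 0:
            raise ValueError("weights must be > 0")
        for name in ("specificity", "case_top_fraction", "control_bottom_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")


@dataclass(frozen=True)
class VkrAssessment:
    """Outcome of evaluating the decision rule for one knee-year."""

    knee_id: str
    t0_month: int
    branch: Optional[str]
    qol_max: Optional[float]
    composite_score: Optional[float]
    cond1_below_threshold: bool
    cond2_worse_than_baseline: bool
    cond3_next_year_sustained: bool
    is_case: bool
    evaluable: bool
    attributed_month: int = 0

    def __post_init__(self) -> None:
        expected = (
            self.evaluable
            and self.cond1_below_threshold
            and self.cond2_worse_than_baseline
            and self.cond3_next_year_sustained
        )
        if self.is_case != expected:
            raise ValueError("is_case must equal cond1 & cond2 & cond3 when evaluable")


def composite_score(
    kp_t0: float,
    kp_tm1: float,
    qol_t0: float,
    qol_tm1: float,
    params: VkrModelParams = VkrModelParams(),
) -> tuple[str, float]:
    """Branch and composite score for one knee-year.

    Equal current and prior pain routes to the "pain not worse" branch
    (the worsening branch applies only when current pain is strictly
    lower than the prior year's).
    """
    for name, v in (
        ("kp_t0", kp_t0),
        ("kp_tm1", kp_tm1),
        ("qol_t0", qol_t0),
        ("qol_tm1", qol_tm1),
    ):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name}={v} outside [0, 100]")
    qol_max = max(qol_t0, qol_tm1)
    score = kp_t0 + params.qol_weight * qol_max
    if kp_t0 < kp_tm1:
        return PAIN_WORSE, score - params.worsening_weight * abs(kp_tm1 - kp_t0)
    return PAIN_NOT_WORSE, score


def evaluate_vkr(
    knee: KneeSeries,
    t0_month: int,
    params: VkrModelParams = VkrModelParams(),
) -> VkrAssessment:
    """Evaluate the decision rule at visit ``t0_month``.

    Requires the scheduled prior (t0-12), baseline (0) and next
    (t0+12) visits to exist in the schedule; case status is attributed
    to month ``t0_month + 12``.
    """
    if t0_month == 0:
        raise ValueError("t0_month=0 has no prior visit")
    if t0_month not in MONTHS or t0_month + 12 not in MONTHS:
        raise ValueError(
            f"t0_month={t0_month} lacks a scheduled prior or next visit"
        )
    attributed = t0_month + 12
    visits = {m: knee.pro_at(m) for m in (0, t0_month - 12, t0_month, attributed)}
    kr_by_next = (
        knee.surgical_kr_month is not None and knee.surgical_kr_month <= attributed
    )
    evaluable = not kr_by_next and all(
        v is not None and v.present for v in visits.values()
    )
    if not evaluable:
        # Report the score when t0/t-1 are available, for audit only.
        branch = score = qmax = None
        v0, vm1 = visits[t0_month], visits[t0_month - 12]
        if v0 is not None and v0.present and vm1 is not None and vm1.present:
            branch, score = composite_score(
                v0.koos_pain, vm1.koos_pain, v0.koos_qol, vm1.koos_qol, params
            )
            qmax = max(v0.koos_qol, vm1.koos_qol)
        return VkrAssessment(
            knee_id=knee.knee_id,
            t0_month=t0_month,
            branch=branch,
            qol_max=qmax,
            composite_score=score,
            cond1_below_threshold=False,
            cond2_worse_than_baseline=False,
            cond3_next_year_sustained=False,
            is_case=False,
            evaluable=False,
            attributed_month=attributed,
        )
    vb, vm1, v0, v1 = (visits[m] for m in (0, t0_month - 12, t0_month, attributed))
    branch, score = composite_score(
        v0.koos_pain, vm1.koos_pain, v0.koos_qol, vm1.koos_qol, params
    )
    cond1 = score < params.threshold
    cond2 = v0.koos_pain < vb.koos_pain and v0.koos_qol < vb.koos_qol
    cond3 = v1.koos_pain <= v0.koos_pain and v1.koos_qol <= v0.koos_qol
    return VkrAssessment(
        knee_id=knee.knee_id,
        t0_month=t0_month,
        branch=branch,
        qol_max=max(v0.koos_qol, vm1.koos_qol),
        composite_score=score,
        cond1_below_threshold=cond1,
        cond2_worse_than_baseline=cond2,
        cond3_next_year_sustained=cond3,
        is_case=cond1 and cond2 and cond3,
        evaluable=True,
        attributed_month=attributed,
    )


def first_case_month(
    knee: KneeSeries, params: VkrModelParams = VkrModelParams()
) -> Optional[int]:
    """Smallest attributed month at which the knee is a vKR case, or None."""
    for t0 in MONTHS[1:-1]:
        if evaluate_vkr(knee, t0, params).is_case:
            return t0 + 12
    return None


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of specificity-based threshold calibration."""

    threshold: float
    false_positive_rate: float
    sensitivity: Optional[float] = None


def calibrate_threshold(
    nonkr_scores: Sequence[float],
    kr_scores: Optional[Sequence[float]] = None,
    specificity: float = 0.90,
) -> ThresholdCalibration:
    """Empirical score threshold achieving at least the given specificity.

    Lower scores indicate higher surgical-KR risk, so a knee is flagged
    when its score falls strictly *below* the threshold.  The threshold
    is the lower empirical (1 - specificity)-quantile of the non-KR
    scores (no interpolation), which guarantees that the achieved
    false-positive rate (fraction of non-KR knees strictly below) is at
    most 1 - specificity.
    """
    scores = np.asarray(nonkr_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("nonkr_scores must be non-empty")
    if not (0.0 < specificity <= 1.0):
        raise ValueError("specificity must be in (0, 1]")
    srt = np.sort(scores)
    k = math.ceil((1.0 - specificity) * scores.size)
    threshold = float(srt[0] if k <= 0 else srt[k - 1])
    fpr = float(np.mean(scores < threshold))
    sens = None
    if kr_scores is not None:
        kr = np.asarray(kr_scores, dtype=float)
        if kr.size:
            sens = float(np.mean(kr < threshold))
    return ThresholdCalibration(threshold, fpr, sens)


def maintenance_status(
    knee: KneeSeries, params: VkrModelParams = VkrModelParams()
) -> str:
    """72 M maintenance status for a knee that first became a case at 60 M.

    Re-applies the sustainment comparison (condition 3's non-strict
    form) one cycle on: the knee "maintained" (vKR+/+) iff KOOS pain
    and QoL at 72 M are less than or equal to their 60 M values.  The
    below-threshold score condition is *not* re-checked at 60 M; only
    the sustainment comparison is applied (documented design choice).
    """
    v60, v72 = knee.pro_at(60), knee.pro_at(72)
    if v60 is None or not v60.present:
        raise MissingVisitError(f"{knee.knee_id}: 60 M PRO visit missing")
    if v72 is None or not v72.present:
        raise MissingVisitError(f"{knee.knee_id}: 72 M PRO visit missing")
    if v72.koos_pain <= v60.koos_pain and v72.koos_qol <= v60.koos_qol:
        return MAINTAINED
    return NOT_MAINTAINED


def maintenance_counts(statuses: Sequence[str]) -> dict[str, int]:
    """Tally maintenance statuses; 'total' is the matched case count."""
    c = Counter(statuses)
    unknown = set(c) - {MAINTAINED, NOT_MAINTAINED}
    if unknown:
        raise ValueError(f"unknown statuses: {sorted(unknown)}")
    return {
        MAINTAINED: c[MAINTAINED],
        NOT_MAINTAINED: c[NOT_MAINTAINED],
        "total": c[MAINTAINED] + c[NOT_MAINTAINED],
    }
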