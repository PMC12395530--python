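"""Shared fixtures: factories for hand-constructed knees and cohorts."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pytest

from vkrpipe import (
    MONTHS,
    SUBREGIONS,
    CartilageVisit,
    KneeSeries,
    ProVisit,
    RadiographicBaseline,
)


def flat_thickness(value: float = 1500.0) -> dict[str, float]:
    return {s: value for s in SUBREGIONS}


@pytest.fixture
def make_knee():
    """Factory for a KneeSeries with explicit per-month scores.

    ``kp``/``qol`` map month -> score (defaults 80/70); ``thickness``
    maps month -> flat value or full subregion dict; ``missing_pro``
    and ``unreadable`` are collections of months to knock out.
    """

    def _make(
        knee_id: str = "P00001-R",
        *,
        kp: Optional[Mapping[int, float]] = None,
        qol: Optional[Mapping[int, float]] = None,
        months: Sequence[int] = MONTHS,
        missing_pro: Sequence[int] = (),
        thickness: Optional[Mapping[int, object]] = None,
        unreadable: Sequence[int] = (),
        mjsw: Optional[Mapping[int, float]] = None,
        klg: Optional[int] = 2,
        jsn: tuple[int, int] = (1, 0),
        sex: str = "F",
        age: float = 60.0,
        kr_month: Optional[int] = None,
        coverage: bool = True,
        bmi: float = 27.0,
    ) -> KneeSeries:
        kp = dict(kp or {})
        qol = dict(qol or {})
        pro_visits = []
        cart_visits = []
        for m in months:
            if kr_month is not None and m >= kr_month:
                continue
            if m in missing_pro:
                pro_visits.append(ProVisit(m, None, None, None, None, present=False))
            else:
                pro_visits.append(
                    ProVisit(m, kp.get(m, 80.0), qol.get(m, 70.0), 5.0, bmi)
                )
            if m in unreadable:
                cart_visits.append(CartilageVisit(m, {}, None, readable=False))
            else:
                th = (thickness or {}).get(m, 1500.0)
                if not isinstance(th, dict):
                    th = flat_thickness(float(th))
                cart_visits.append(
                    CartilageVisit(m, th, (mjsw or {}).get(m, 4.0))
                )
        pid, side = knee_id.rsplit("-", 1)
        return KneeSeries(
            participant_id=pid,
            knee_id=knee_id,
            side=side,
            sex=sex,
            age_baseline=age,
            radiographic=(
                RadiographicBaseline.from_grades(klg, *jsn) if klg is not None else None
            ),
            pro_visits=pro_visits,
            cartilage_visits=cart_visits,
            surgical_kr_month=kr_month,
            continuous_coverage=coverage,
        )

    return _make


#: PRO trajectory that first meets the vKR case definition at t0 = 48 M
#: (attributed month 60) and at no earlier visit.
CASE_KP = {0: 90.0, 12: 88.0, 24: 85.0, 36: 80.0, 48: 55.0, 60: 50.0, 72: 48.0}
CASE_QOL = {0: 80.0, 12: 78.0, 24: 77.0, 36: 75.0, 48: 40.0, 60: 38.0, 72: 36.0}
#: Flat high-score trajectory: never a case, lowest-risk stratum.
CLEAN_KP = {m: 95.0 for m in MONTHS}
CLEAN_QOL = {m: 85.0 for m in MONTHS}
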