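"""Femorotibial cartilage-thickness aggregation and change metrics.

Cartilage morphometry pipelines report the mean thickness of 16
femorotibial subregions per knee: five subregions (central, external,
internal, anterior, posterior) on each tibial plateau and three
(central, external, internal) on each weight-bearing femoral condyle.
This module aggregates those subregions into the standard region
variables (cMFTC, MFTC and their lateral analogues, plus the individual
plates), computes interval changes in micrometres (loss negative), the
location-independent thinning/thickening scores, and radiographic
minimal medial joint-space-width (mJSW) change.

Unit discipline: every output of this module is in micrometres; the
single mm-to-um conversion for mJSW happens in :func:`mjsw_change`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .cohort import CartilageVisit, KneeSeries

MM_TO_UM = 1000.0

#: The fixed 16-subregion vocabulary.  Tibial plates carry five
#: subregions (c/e/i/a/p), femoral condyles three (c/e/i).
TIBIAL_MEDIAL = ("cMT", "eMT", "iMT", "aMT", "pMT")
TIBIAL_LATERAL = ("cLT", "eLT", "iLT", "aLT", "pLT")
FEMORAL_MEDIAL = ("ccMF", "ecMF", "icMF")
FEMORAL_LATERAL = ("ccLF", "ecLF", "icLF")
SUBREGIONS = TIBIAL_MEDIAL + TIBIAL_LATERAL + FEMORAL_MEDIAL + FEMORAL_LATERAL


@dataclass(frozen=True)
class RegionSpec:
    """A named cartilage region built from one or two plates.

    A plate is a group of subregions whose thicknesses are averaged
    (equal weights by default; pass explicit ``weights`` to use
    area-weighted means).  The region value is the *sum* over plates,
    so a femorotibial compartment is tibial-plate + femoral-plate,
    mirroring the convention cMFTC = cMT + ccMF.
    """

    name: str
    plates: tuple[tuple[str, ...], ...]
    weights: Optional[tuple[tuple[float, ...], ...]] = None

    def __post_init__(self) -> None:
        if not self.plates or any(not p for p in self.plates):
            raise ValueError(f"region {self.name!r}: plates must be non-empty")
        for plate in self.plates:
            unknown = set(plate) - set(SUBREGIONS)
            if unknown:
                raise ValueError(
                    f"region {self.name!r}: unknown subregions {sorted(unknown)}"
                )
        if self.weights is not None:
            if len(self.weights) != len(self.plates) or any(
                len(w) != len(p) for w, p in zip(self.weights, self.plates)
            ):
                raise ValueError(f"region {self.name!r}: weights do not match plates")

    @property
    def member_subregions(self) -> frozenset[str]:
        return frozenset(s for plate in self.plates for s in plate)


REGIONS: dict[str, RegionSpec] = {
    spec.name: spec
    for spec in (
        RegionSpec("cMT", (("cMT",),)),
        RegionSpec("ccMF", (("ccMF",),)),
        RegionSpec("cLT", (("cLT",),)),
        RegionSpec("ccLF", (("ccLF",),)),
        RegionSpec("cMFTC", (("cMT",), ("ccMF",))),
        RegionSpec("cLFTC", (("cLT",), ("ccLF",))),
        RegionSpec("MT", (TIBIAL_MEDIAL,)),
        RegionSpec("LT", (TIBIAL_LATERAL,)),
        RegionSpec("cMF", (FEMORAL_MEDIAL,)),
        RegionSpec("cLF", (FEMORAL_LATERAL,)),
        RegionSpec("MFTC", (TIBIAL_MEDIAL, FEMORAL_MEDIAL)),
        RegionSpec("LFTC", (TIBIAL_LATERAL, FEMORAL_LATERAL)),
    )
}


@dataclass(frozen=True)
class IntervalChange:
    """Change in a region's thickness over one observation interval.

    ``delta`` is in micrometres, negative for loss, and is ``None``
    (``defined`` False) when either visit is missing or unreadable; the
    knee is then dropped pairwise from that variable, never imputed.
    """

    knee_id: str
    region: str
    from_month: int
    to_month: int
    delta: Optional[float]
    defined: bool = True

    def __post_init__(self) -> None:
        if self.to_month <= self.from_month:
            raise ValueError("to_month must exceed from_month")
        if self.defined and self.delta is None:
            raise ValueError("defined IntervalChange requires a delta")


@dataclass(frozen=True)
class ThinningScores:
    """Location-independent thinning/thickening scores over an interval."""

    knee_id: str
    from_month: int
    to_month: int
    thinning: Optional[float]
    thickening: Optional[float]
    defined: bool = True


def region_thickness(
    visit: "CartilageVisit",
    region: RegionSpec,
) -> float:
    """Aggregate a visit's subregion thicknesses into a region value (um).

    Plate means use the region's weights (equal by default); the region
    value is the sum of plate means.
    """
    if not visit.readable:
        raise ValueError(f"visit at month {visit.visit_month} is not readable")
    total = 0.0
    for i, plate in enumerate(region.plates):
        plate_weights = region.weights[i] if region.weights is not None else None
        acc = 0.0
        wsum = 0.0
        for j, sub in enumerate(plate):
            if sub not in visit.thickness:
                raise ValueError(f"missing subregion {sub!r} in visit")
            w = 1.0 if plate_weights is None else plate_weights[j]
            acc += w * visit.thickness[sub]
            wsum += w
        total += acc / wsum
    return total


def interval_change(
    knee: "KneeSeries",
    region: RegionSpec,
    from_month: int,
    to_month: int,
) -> IntervalChange:
    """Region thickness change to_month minus from_month, in um (loss < 0)."""
    v0 = knee.cart_at(from_month)
    v1 = knee.cart_at(to_month)
    if v0 is None or v1 is None or not v0.readable or not v1.readable:
        return IntervalChange(knee.knee_id, region.name, from_month, to_month, None, False)
    delta = region_thickness(v1, region) - region_thickness(v0, region)
    return IntervalChange(knee.knee_id, region.name, from_month, to_month, delta)


def thinning_thickening_scores(
    knee: "KneeSeries",
    from_month: int,
    to_month: int,
    sdc_threshold: float = 0.0,
) -> ThinningScores:
    """Signed sums of negative/positive subregion changes over an interval.

    ``thinning`` is the sum of all subregion changes below
    ``-sdc_threshold`` (so thinning <= 0), ``thickening`` the sum of all
    changes above ``+sdc_threshold``.  With the default threshold of 0
    the two scores partition the total summed subregion change exactly.
    The threshold hook exists because some implementations only count
    changes beyond a smallest detectable change.
    """
    if sdc_threshold < 0:
        raise ValueError("sdc_threshold must be >= 0")
    if to_month <= from_month:
        raise ValueError("to_month must exceed from_month")
    v0 = knee.cart_at(from_month)
    v1 = knee.cart_at(to_month)
    if v0 is None or v1 is None or not v0.readable or not v1.readable:
        return ThinningScores(knee.knee_id, from_month, to_month, None, None, False)
    thinning = 0.0
    thickening = 0.0
    for sub in SUBREGIONS:
        if sub not in v0.thickness or sub not in v1.thickness:
            raise ValueError(f"missing subregion {sub!r}")
        d = v1.thickness[sub] - v0.thickness[sub]
        if d < -sdc_threshold:
            thinning += d
        elif d > sdc_threshold:
            thickening += d
    return ThinningScores(knee.knee_id, from_month, to_month, thinning, thickening)


def mjsw_change(
    knee: "KneeSeries",
    from_month: int,
    to_month: int,
) -> Optional[float]:
    """Minimal medial joint-space-width change in um (loss negative).

    Returns ``None`` when either visit lacks an mJSW measurement; the
    pair is then excluded from the mJSW sub-analysis.
    """
    if to_month <= from_month:
        raise ValueError("to_month must exceed from_month")
    v0 = knee.cart_at(from_month)
    v1 = knee.cart_at(to_month)
    if (
        v0 is None
        or v1 is None
        or v0.mjsw_medial is None
        or v1.mjsw_medial is None
    ):
        return None
    return (v1.mjsw_medial - v0.mjsw_medial) * MM_TO_UM
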