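"""Synthetic longitudinal knee-OA cohort generator.

Emulates an OAI-like cohort: annual visits at months 0-72, two knees
per participant with within-person correlation, patient-reported
outcomes (KOOS pain / KOOS quality of life, both 0-100 with higher =
better; WOMAC pain 0-20 with higher = worse), per-subregion
femorotibial cartilage thickness (um), radiographic baseline status
(Kellgren-Lawrence grade, joint-space-narrowing grades, minimal medial
joint-space width), surgical knee-replacement events, health-coverage
flags, loss to follow-up and intermittent visit missingness.

The generative model (documented in full in docs/methods.md):

* a participant-level severity factor is shared between knees so that
  the two knee-level latent severities correlate at ``within_person_corr``;
* latent severity shifts the *level* of the symptom trajectories
  (intercept); the linear decline slope is knee-specific noise, so
  symptom *change* before 48 M is severity-independent;
* "progressor" knees (the top ``progressor_fraction`` of latent
  severity) additionally accelerate their decline over the last two
  simulated years (months > 48), producing the steep pre-endpoint
  symptom worsening the virtual-KR definition keys on;
* 2-year central-medial cartilage change is Gaussian with group means
  and SDs taken from ``SimConfig`` (progressors vs non-progressors),
  decomposed into a stable knee-level loss rate plus annual shocks so
  that *every* 2-year window has exactly the configured mean and SD;
  the knee-level rate is coupled to latent severity with correlation
  ``symptom_structure_corr``;
* surgical KR events follow a logistic function of latent severity, and
  all data after a surgical KR are truncated.

All randomness flows from one root seed through named, id-keyed
substreams, so adding participants never perturbs existing knees and
identical configuration yields identical cohorts.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .metrics import (
    FEMORAL_LATERAL,
    FEMORAL_MEDIAL,
    SUBREGIONS,
    TIBIAL_LATERAL,
    TIBIAL_MEDIAL,
)

logger = logging.getLogger(__name__)

#: The seven scheduled visit months.
MONTHS = (0, 12, 24, 36, 48, 60, 72)

# Named sub-stream tags (see _rng); values are arbitrary but frozen.
_STREAM_PARTICIPANT = 11
_STREAM_KNEE = 12
_STREAM_MISSING = 13
_STREAM_PAIRS = 14


def _rng(seed: int, *path: int) -> np.random.Generator:
    """A generator keyed by the root seed and a named integer path."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(p) & 0xFFFFFFFF for p in path]])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProVisit:
    """One attended (or missed) patient-reported-outcome visit."""

    visit_month: int
    koos_pain: Optional[float]
    koos_qol: Optional[float]
    womac_pain: Optional[float]
    bmi: Optional[float]
    present: bool = True

    def __post_init__(self) -> None:
        if self.visit_month not in MONTHS:
            raise ValueError(f"visit_month {self.visit_month} not a scheduled month")
        if self.present:
            for name, val, lo, hi in (
                ("koos_pain", self.koos_pain, 0.0, 100.0),
                ("koos_qol", self.koos_qol, 0.0, 100.0),
                ("womac_pain", self.womac_pain, 0.0, 20.0),
            ):
                if val is None or not (lo <= val <= hi):
                    raise ValueError(f"{name}={val!r} outside [{lo}, {hi}]")
            if self.bmi is None or not (10.0 < self.bmi < 80.0):
                raise ValueError(f"bmi={self.bmi!r} outside (10, 80)")


@dataclass(frozen=True)
class CartilageVisit:
    """One MRI visit: 16 subregion mean thicknesses (um) plus mJSW (mm)."""

    visit_month: int
    thickness: dict[str, float]
    mjsw_medial: Optional[float]
    readable: bool = True

    def __post_init__(self) -> None:
        if self.visit_month not in MONTHS:
            raise ValueError(f"visit_month {self.visit_month} not a scheduled month")
        if self.readable:
            if set(self.thickness) != set(SUBREGIONS):
                raise ValueError("thickness must cover exactly the 16 subregions")
            for sub, val in self.thickness.items():
                if not (0.0 <= val < 10000.0):
                    raise ValueError(f"thickness[{sub}]={val} outside [0, 10000)")
            if self.mjsw_medial is not None and self.mjsw_medial < 0:
                raise ValueError("mjsw_medial must be >= 0")


def klg_stratum(klg: int) -> str:
    """Collapse KLG 0-4 to the matching strata '0-1', '2', '3', '4'."""
    if klg not in (0, 1, 2, 3, 4):
        raise ValueError(f"klg={klg} outside 0-4")
    return "0-1" if klg <= 1 else str(klg)


def jsn_dominant(jsn_medial: int, jsn_lateral: int) -> str:
    """Compartment with the greatest joint-space-narrowing grade."""
    for g in (jsn_medial, jsn_lateral):
        if g not in (0, 1, 2, 3):
            raise ValueError(f"JSN grade {g} outside 0-3")
    if jsn_medial == jsn_lateral == 0:
        return "none"
    if jsn_medial == jsn_lateral:
        return "both"
    return "medial" if jsn_medial > jsn_lateral else "lateral"


@dataclass(frozen=True)
class RadiographicBaseline:
    """Baseline radiographic status used for matching strata."""

    klg: int
    klg_stratum: str
    jsn_medial: int
    jsn_lateral: int
    jsn_dominant: str

    def __post_init__(self) -> None:
        if self.klg_stratum != klg_stratum(self.klg):
            raise ValueError("klg_stratum inconsistent with klg")
        if self.jsn_dominant != jsn_dominant(self.jsn_medial, self.jsn_lateral):
            raise ValueError("jsn_dominant inconsistent with JSN grades")

    @classmethod
    def from_grades(
        cls, klg: int, jsn_medial: int, jsn_lateral: int
    ) -> "RadiographicBaseline":
        return cls(
            klg=klg,
            klg_stratum=klg_stratum(klg),
            jsn_medial=jsn_medial,
            jsn_lateral=jsn_lateral,
            jsn_dominant=jsn_dominant(jsn_medial, jsn_lateral),
        )


@dataclass
class KneeSeries:
    """One knee's longitudinal record.

    ``is_progressor`` and ``latent_severity`` are simulation ground
    truth carried for validation; they are never consulted by the
    classification, selection or analysis stages.
    """

    participant_id: str
    knee_id: str
    side: str
    sex: str
    age_baseline: float
    radiographic: Optional[RadiographicBaseline]
    pro_visits: list[ProVisit] = field(default_factory=list)
    cartilage_visits: list[CartilageVisit] = field(default_factory=list)
    surgical_kr_month: Optional[int] = None
    continuous_coverage: bool = True
    is_progressor: Optional[bool] = None
    latent_severity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        for visits in (self.pro_visits, self.cartilage_visits):
            months = [v.visit_month for v in visits]
            if len(months) != len(set(months)):
                raise ValueError(f"{self.knee_id}: duplicate visit months")
            if self.surgical_kr_month is not None and any(
                m >= self.surgical_kr_month for m in months
            ):
                raise ValueError(
                    f"{self.knee_id}: visit data on/after surgical KR month"
                )

    def pro_at(self, month: int) -> Optional[ProVisit]:
        for v in self.pro_visits:
            if v.visit_month == month:
                return v
        return None

    def cart_at(self, month: int) -> Optional[CartilageVisit]:
        for v in self.cartilage_visits:
            if v.visit_month == month:
                return v
        return None


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator configuration.

    The cartilage-change defaults are the published case/control 2-year
    central-medial femorotibial (cMFTC) means and SDs; the KLG
    distribution default is the published case-knee baseline
    distribution.  ``rate_variance_fraction`` is the share of 2-year
    cartilage-change variance carried by a stable knee-level loss rate
    (the remainder is annual measurement/biological shock); it bounds
    the achievable ``symptom_structure_corr`` at its square root.
    """

    n_participants: int = 4796
    seed: int = 0
    progressor_fraction: float = 0.10
    case_loss_mean_2y: float = -151.0
    case_loss_sd_2y: float = 337.0
    control_loss_mean_2y: float = -38.0
    control_loss_sd_2y: float = 249.0
    within_person_corr: float = 0.5
    symptom_structure_corr: float = 0.0
    missing_visit_prob: float = 0.05
    klg_probs: tuple[float, ...] = (0.26, 0.06, 0.26, 0.28, 0.14)
    dropout_prob: float = 0.03
    rate_variance_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for name in (
            "progressor_fraction",
            "missing_visit_prob",
            "dropout_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("within_person_corr", "symptom_structure_corr"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} outside [0, 1)")
        if self.case_loss_sd_2y <= 0 or self.control_loss_sd_2y <= 0:
            raise ValueError("loss SDs must be > 0")
        if len(self.klg_probs) != 5 or any(p < 0 for p in self.klg_probs):
            raise ValueError("klg_probs must be 5 non-negative probabilities")
        if abs(sum(self.klg_probs) - 1.0) > 1e-9:
            raise ValueError("klg_probs must sum to 1")
        if not (0.0 < self.rate_variance_fraction <= 1.0):
            raise ValueError("rate_variance_fraction must be in (0, 1]")
        if self.symptom_structure_corr**2 > self.rate_variance_fraction:
            raise ValueError(
                "symptom_structure_corr^2 may not exceed rate_variance_fraction"
            )


# Fixed trajectory constants (levels/slopes in score points, see methods).
_KP_INTERCEPT, _KP_SEVERITY, _KP_SLOPE, _KP_SLOPE_SD, _KP_NOISE = 82.0, 8.0, -1.3, 0.8, 4.0
_QOL_INTERCEPT, _QOL_SEVERITY, _QOL_SLOPE, _QOL_SLOPE_SD, _QOL_NOISE = 62.0, 7.0, -1.6, 0.9, 4.5
_ACCEL_PER_YEAR = 9.0  # extra decline per year after month 48 for progressors
_RELAPSE_P = 0.5  # progressors whose symptoms rebound between 60 and 72 M
_RELAPSE_REBOUND = 6.0  # score points regained at 72 M by relapsing knees
_KR_LOGIT_INTERCEPT, _KR_LOGIT_SLOPE = -4.6, 1.5
_KR_MONTHS = (6, 12, 24, 36, 48, 60, 72)
_KR_MONTH_PROBS = (0.05, 0.10, 0.12, 0.15, 0.18, 0.20, 0.20)
_BASELINE_PRO_MISSING_P = 0.005
_RADIOGRAPH_MISSING_P = 0.02
_NO_COVERAGE_P = 0.05

# Subregion change shares of the central-medial annual increment.
_CMT_SHARE, _CCMF_SHARE = 0.47, 0.53
_PERIPH_TIBIAL_SHARE, _PERIPH_FEMORAL_SHARE = 0.30, 0.24
_LATERAL_SCALE = 0.55
_SPLIT_NOISE, _PERIPH_NOISE, _LATERAL_NOISE = 40.0, 35.0, 60.0
# mJSW annual change (um) linked to the central-medial annual increment.
_MJSW_SLOPE, _MJSW_DRIFT, _MJSW_NOISE = 1.59, -108.75, 275.0


def _latent_to_group_params(config: SimConfig, progressor: bool) -> tuple[float, float]:
    if progressor:
        return config.case_loss_mean_2y, config.case_loss_sd_2y
    return config.control_loss_mean_2y, config.control_loss_sd_2y


def _annual_cmftc_increments(
    config: SimConfig,
    z_resid: float,
    progressor: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Six annual cMFTC increments whose every 2-year sum has the
    configured group mean and SD.

    Decomposition: a stable knee-level rate (fraction ``a`` of the
    2-year variance) plus independent annual shocks.  ``z_resid`` is
    the knee's *within-group* standardized severity residual (zero
    mean, unit variance given progressor status); the knee-level rate
    is anti-correlated with it at ``symptom_structure_corr / sqrt(a)``
    so that corr(severity, 2-year change) = -symptom_structure_corr
    within each group (higher severity -> greater loss) while the group
    mean and SD stay exactly at their configured values.
    """
    mu, sd = _latent_to_group_params(config, progressor)
    a = config.rate_variance_fraction
    rho = config.symptom_structure_corr / math.sqrt(a)
    m = -rho * z_resid + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal()
    shocks = rng.normal(size=6)
    return mu / 2.0 + sd * math.sqrt(a) * m / 2.0 + sd * math.sqrt((1.0 - a) / 2.0) * shocks


def _jsn_grades(klg: int, rng: np.random.Generator) -> tuple[int, int]:
    """JSN grades loosely consistent with the KLG (narrowing from KLG >= 2)."""
    if klg <= 1:
        return 0, 0
    primary = klg - 1
    secondary = int(max(0, primary - 1 - rng.integers(0, 2)))
    if rng.random() < 0.75:
        return primary, secondary
    return secondary, primary


class _ClipCounter:
    def __init__(self) -> None:
        self.count = 0

    def clip(self, values: np.ndarray, lo: float, hi: float) -> np.ndarray:
        clipped = np.clip(values, lo, hi)
        self.count += int(np.sum(clipped != values))
        return clipped


def _simulate_knee(
    config: SimConfig,
    pid: str,
    i: int,
    k: int,
    side: str,
    sex: str,
    age: float,
    u_participant: float,
    bmi_base: float,
    z_cut: float,
    group_moments: dict[bool, tuple[float, float]],
    clips: _ClipCounter,
) -> KneeSeries:
    rng = _rng(config.seed, _STREAM_KNEE, i, k)
    rho_w = config.within_person_corr
    z = math.sqrt(rho_w) * u_participant + math.sqrt(1.0 - rho_w) * rng.normal()
    progressor = bool(z > z_cut)
    # Standardized within-group severity residual (truncated-normal moments).
    g_mean, g_sd = group_moments[progressor]
    z_resid = (z - g_mean) / g_sd if g_sd > 0 else 0.0

    # Radiographic baseline (independent of severity; see methods note).
    if rng.random() < _RADIOGRAPH_MISSING_P:
        radiographic = None
    else:
        klg = int(rng.choice(5, p=np.asarray(config.klg_probs)))
        jm, jl = _jsn_grades(klg, rng)
        radiographic = RadiographicBaseline.from_grades(klg, jm, jl)

    years = np.array(MONTHS, dtype=float) / 12.0
    kp_slope = _KP_SLOPE + _KP_SLOPE_SD * rng.normal()
    qol_slope = _QOL_SLOPE + _QOL_SLOPE_SD * rng.normal()
    kp = (
        _KP_INTERCEPT
        - _KP_SEVERITY * z
        + kp_slope * years
        + _KP_NOISE * rng.normal(size=len(MONTHS))
    )
    qol = (
        _QOL_INTERCEPT
        - _QOL_SEVERITY * z
        + qol_slope * years
        + _QOL_NOISE * rng.normal(size=len(MONTHS))
    )
    if progressor:
        accel = _ACCEL_PER_YEAR * np.maximum(years - 4.0, 0.0)
        # About half of progressors rebound after the endpoint year, so
        # the 72 M sustainment check splits the case group.
        if rng.random() < _RELAPSE_P:
            accel[6] = accel[5] - _RELAPSE_REBOUND
        kp = kp - accel
        qol = qol - accel
    kp = clips.clip(kp, 0.0, 100.0)
    qol = clips.clip(qol, 0.0, 100.0)
    womac = clips.clip(
        0.15 * (100.0 - kp) + 1.5 * rng.normal(size=len(MONTHS)), 0.0, 20.0
    )
    bmi = clips.clip(
        bmi_base + 0.10 * years + 0.3 * rng.normal(size=len(MONTHS)), 11.0, 79.0
    )
    baseline_pro_missing = rng.random() < _BASELINE_PRO_MISSING_P

    # Cartilage thickness trajectories.
    inc_med = _annual_cmftc_increments(config, z_resid, progressor, rng)
    inc_lat = _LATERAL_SCALE * inc_med + _LATERAL_NOISE * rng.normal(size=6)
    w_med = _SPLIT_NOISE * rng.normal(size=6)
    w_lat = _SPLIT_NOISE * rng.normal(size=6)
    incr: dict[str, np.ndarray] = {
        "cMT": _CMT_SHARE * inc_med + w_med,
        "ccMF": _CCMF_SHARE * inc_med - w_med,
        "cLT": _CMT_SHARE * inc_lat + w_lat,
        "ccLF": _CCMF_SHARE * inc_lat - w_lat,
    }
    for sub in TIBIAL_MEDIAL[1:]:
        incr[sub] = _PERIPH_TIBIAL_SHARE * inc_med + _PERIPH_NOISE * rng.normal(size=6)
    for sub in FEMORAL_MEDIAL[1:]:
        incr[sub] = _PERIPH_FEMORAL_SHARE * inc_med + _PERIPH_NOISE * rng.normal(size=6)
    for sub in TIBIAL_LATERAL[1:]:
        incr[sub] = _PERIPH_TIBIAL_SHARE * inc_lat + _PERIPH_NOISE * rng.normal(size=6)
    for sub in FEMORAL_LATERAL[1:]:
        incr[sub] = _PERIPH_FEMORAL_SHARE * inc_lat + _PERIPH_NOISE * rng.normal(size=6)

    base: dict[str, float] = {}
    for sub in SUBREGIONS:
        if sub in ("cMT", "cLT"):
            mu_b, sd_b = 1750.0, 250.0
        elif sub in ("ccMF", "ccLF"):
            mu_b, sd_b = 1850.0, 280.0
        elif sub in TIBIAL_MEDIAL or sub in TIBIAL_LATERAL:
            mu_b, sd_b = 1500.0, 200.0
        else:
            mu_b, sd_b = 1700.0, 230.0
        base[sub] = float(max(200.0, mu_b + sd_b * rng.normal()))

    thickness_by_visit: list[dict[str, float]] = []
    for v in range(len(MONTHS)):
        row = {}
        for sub in SUBREGIONS:
            val = base[sub] + float(np.sum(incr[sub][:v]))
            row[sub] = float(min(max(val, 0.0), 9999.0))
        thickness_by_visit.append(row)

    mjsw_base = float(np.clip(3.9 + 1.2 * rng.normal(), 0.5, 8.0))
    mjsw_annual_um = _MJSW_DRIFT + _MJSW_SLOPE * inc_med + _MJSW_NOISE * rng.normal(size=6)
    mjsw = [mjsw_base]
    for v in range(6):
        mjsw.append(max(0.2, mjsw[-1] + mjsw_annual_um[v] / 1000.0))

    # Surgical KR and loss to follow-up.
    kr_month: Optional[int] = None
    if rng.random() < float(expit(_KR_LOGIT_INTERCEPT + _KR_LOGIT_SLOPE * z)):
        kr_month = int(rng.choice(_KR_MONTHS, p=_KR_MONTH_PROBS))
    dropped_out = rng.random() < config.dropout_prob
    coverage = rng.random() >= _NO_COVERAGE_P

    pro_visits: list[ProVisit] = []
    cart_visits: list[CartilageVisit] = []
    for v, month in enumerate(MONTHS):
        if kr_month is not None and month >= kr_month:
            break
        if dropped_out and month > 0:
            break
        if month == 0 and baseline_pro_missing:
            pro_visits.append(ProVisit(month, None, None, None, None, present=False))
        else:
            pro_visits.append(
                ProVisit(
                    month,
                    float(kp[v]),
                    float(qol[v]),
                    float(womac[v]),
                    float(bmi[v]),
                )
            )
        cart_visits.append(
            CartilageVisit(month, thickness_by_visit[v], float(mjsw[v]))
        )

    return KneeSeries(
        participant_id=pid,
        knee_id=f"{pid}-{side}",
        side=side,
        sex=sex,
        age_baseline=age,
        radiographic=radiographic,
        pro_visits=pro_visits,
        cartilage_visits=cart_visits,
        surgical_kr_month=kr_month,
        continuous_coverage=coverage,
        is_progressor=progressor,
        latent_severity=z,
    )


def generate_cohort(config: SimConfig) -> list[KneeSeries]:
    """Generate the full two-knees-per-participant cohort.

    Deterministic: identical config (including seed) yields identical
    cohorts, and adding participants does not perturb existing knees.
    """
    if config.n_participants == 0:
        return []
    f = config.progressor_fraction
    z_cut = float(norm.ppf(1.0 - f)) if f > 0 else math.inf
    group_moments: dict[bool, tuple[float, float]] = {}
    for progressor, (a, b) in ((True, (z_cut, math.inf)), (False, (-math.inf, z_cut))):
        if not math.isfinite(a) and not math.isfinite(b):
            group_moments[progressor] = (0.0, 1.0)
        elif (progressor and f == 0) or (not progressor and f == 1):
            group_moments[progressor] = (0.0, 1.0)  # empty group, unused
        else:
            tn = truncnorm(a, b)
            group_moments[progressor] = (float(tn.mean()), float(tn.std()))
    clips = _ClipCounter()
    cohort: list[KneeSeries] = []
    for i in range(config.n_participants):
        prng = _rng(config.seed, _STREAM_PARTICIPANT, i)
        sex = "F" if prng.random() < 0.52 else "M"
        age = float(np.clip(prng.normal(61.0, 9.0), 45.0, 79.0))
        u = float(prng.normal())
        bmi_base = float(np.clip(prng.normal(28.7, 4.8), 16.0, 55.0))
        pid = f"P{i:05d}"
        for k, side in enumerate(("R", "L")):
            cohort.append(
                _simulate_knee(
                    config,
                    pid,
                    i,
                    k,
                    side,
                    sex,
                    age,
                    u,
                    bmi_base,
                    z_cut,
                    group_moments,
                    clips,
                )
            )
    if clips.count:
        logger.info("clipped %d simulated values at score bounds", clips.count)
    return cohort


def inject_missingness(
    cohort: Sequence[KneeSeries], config: SimConfig
) -> list[KneeSeries]:
    """Mark PRO visits absent and MRI visits unreadable at random.

    Each non-baseline visit is hit independently with probability
    ``missing_visit_prob``; month 0 is never touched.  Deterministic
    under the config seed and keyed by knee id, so the same knee is
    always hit the same way regardless of cohort ordering.
    """
    p = config.missing_visit_prob
    out: list[KneeSeries] = []
    for knee in cohort:
        rng = _rng(config.seed, _STREAM_MISSING, zlib.crc32(knee.knee_id.encode()))
        pro_visits: list[ProVisit] = []
        for v in knee.pro_visits:
            if v.visit_month > 0 and v.present and rng.random() < p:
                pro_visits.append(
                    ProVisit(v.visit_month, None, None, None, None, present=False)
                )
            else:
                pro_visits.append(v)
        cart_visits: list[CartilageVisit] = []
        for cv in knee.cartilage_visits:
            if cv.visit_month > 0 and cv.readable and rng.random() < p:
                cart_visits.append(
                    CartilageVisit(cv.visit_month, {}, None, readable=False)
                )
            else:
                cart_visits.append(cv)
        out.append(
            replace(knee, pro_visits=pro_visits, cartilage_visits=cart_visits)
        )
    return out


def sample_matched_changes(
    config: SimConfig, n_pairs: int, seed: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw matched-pair 2-year cMFTC changes from the generator's model.

    Returns ``(case_changes, control_changes)`` in um, each the sum of
    two annual increments from :func:`_annual_cmftc_increments` with
    independent latent severities, i.e. exactly the configured group
    distributions.  Used for statistical validation at pair level
    without simulating full cohorts.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = _rng(config.seed if seed is None else seed, _STREAM_PAIRS)
    cases = np.empty(n_pairs)
    controls = np.empty(n_pairs)
    for j in range(n_pairs):
        inc_c = _annual_cmftc_increments(config, rng.normal(), True, rng)
        inc_k = _annual_cmftc_increments(config, rng.normal(), False, rng)
        cases[j] = inc_c[2] + inc_c[3]
        controls[j] = inc_k[2] + inc_k[3]
    return cases, controls
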