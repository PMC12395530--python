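"""Matched-pair statistics: paired t, 1:1 conditional logistic regression
with cluster-robust sandwich variance, BMI-category adjustment, and the
Kruskal-Wallis sensitivity comparison.

The conditional likelihood for 1:1 matched pairs,

    L(beta) = prod_j exp(beta' x_case_j) / (exp(beta' x_case_j) + exp(beta' x_control_j)),

depends on the covariates only through within-pair differences
d_j = x_case_j - x_control_j and equals an intercept-free logistic
model on d_j with all outcomes one.  The exposure of interest is
pre-divided by the control-group standard deviation so that exp(beta)
is the odds ratio per control-SD.  Participants contributing more than
one knee induce dependence between pairs; the sandwich estimator
aggregates per-pair score contributions over clusters formed by
connected components of shared participant ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit

Z_95 = 1.959963984540054


class SeparationError(RuntimeError):
    """The conditional likelihood is monotone (complete separation)."""


@dataclass(frozen=True)
class PairedComparison:
    """One report row: group summaries, paired t, and conditional-logistic OR."""

    variable: str
    from_month: int
    to_month: int
    n_pairs: int
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    t_stat: Optional[float]
    t_pvalue: Optional[float]
    beta: Optional[float]
    or_per_sd: Optional[float]
    ci95_low: Optional[float]
    ci95_high: Optional[float]
    robust: bool = True
    adjusted: bool = False

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.beta is not None and self.or_per_sd is not None:
            if not math.isclose(self.or_per_sd, math.exp(self.beta), rel_tol=1e-9):
                raise ValueError("or_per_sd must equal exp(beta)")
            if self.ci95_low is not None and not (
                self.ci95_low <= self.or_per_sd <= self.ci95_high
            ):
                raise ValueError("CI must bracket the OR")


def paired_t(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, float, int]:
    """Two-sided paired t-test on case minus control differences."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("case and control value lists must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t requires n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate: all differences identical")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return t, p, n - 1


def bmi_category(bmi: float) -> int:
    """WHO category: 0 normal (<25), 1 overweight [25, 30), 2 obese (>=30)."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    if bmi < 25.0:
        return 0
    if bmi < 30.0:
        return 1
    return 2


def bmi_adjustment_covariates(case_bmi: float, control_bmi: float) -> np.ndarray:
    """Within-pair differences of the overweight/obese indicators."""
    cc, kc = bmi_category(case_bmi), bmi_category(control_bmi)
    return np.array(
        [float(cc == 1) - float(kc == 1), float(cc == 2) - float(kc == 2)]
    )


@dataclass(frozen=True)
class ClogitResult:
    """Fitted 1:1 conditional logistic model on within-pair differences."""

    beta: np.ndarray  # all coefficients; beta[0] is per-control-SD exposure
    cov_model: np.ndarray
    cov_robust: np.ndarray
    n_pairs: int
    n_clusters: int
    converged: bool

    @property
    def beta_exposure(self) -> float:
        return float(self.beta[0])

    @property
    def or_per_sd(self) -> float:
        return math.exp(self.beta_exposure)

    def se(self, robust: bool = True) -> float:
        cov = self.cov_robust if robust else self.cov_model
        return float(math.sqrt(cov[0, 0]))

    def ci95(self, robust: bool = True) -> tuple[float, float]:
        se = self.se(robust)
        b = self.beta_exposure
        return math.exp(b - Z_95 * se), math.exp(b + Z_95 * se)

    def wald_p(self, robust: bool = True) -> float:
        z = self.beta_exposure / self.se(robust)
        return float(2.0 * sps.norm.sf(abs(z)))


def _pair_clusters(
    case_ids: Optional[Sequence[str]],
    control_ids: Optional[Sequence[str]],
    clusters: Optional[Mapping[str, str]],
    n: int,
) -> np.ndarray:
    """Cluster index per pair: connected components over participant ids."""
    if case_ids is None or control_ids is None or clusters is None:
        return np.arange(n)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    pair_parts = []
    for cid, kid in zip(case_ids, control_ids):
        pa = clusters.get(cid, f"knee:{cid}")
        pb = clusters.get(kid, f"knee:{kid}")
        union(pa, pb)
        pair_parts.append(pa)
    roots = [find(p) for p in pair_parts]
    index = {r: i for i, r in enumerate(dict.fromkeys(roots))}
    return np.array([index[r] for r in roots])


def clogit_1to1(
    case_x: Sequence[float],
    control_x: Sequence[float],
    scale_sd: float,
    covariate_diffs: Optional[np.ndarray] = None,
    case_ids: Optional[Sequence[str]] = None,
    control_ids: Optional[Sequence[str]] = None,
    clusters: Optional[Mapping[str, str]] = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ClogitResult:
    """Fit the 1:1 conditional logistic model by Newton iteration.

    ``scale_sd`` (the control-group SD of the exposure) standardizes
    the exposure difference so that exp(beta[0]) is the OR per
    control-SD.  ``covariate_diffs`` (n_pairs x p) appends adjustment
    covariates (already differenced within pair).  ``clusters`` maps
    knee ids to participant ids for the sandwich variance; without it,
    every pair is its own cluster.

    Raises :class:`SeparationError` when the likelihood is monotone
    (all informative difference vectors point the same way along some
    direction), in which case no finite estimate exists.
    """
    x = np.asarray(case_x, dtype=float)
    y = np.asarray(control_x, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("case_x and control_x must be equal-length vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if scale_sd <= 0:
        raise ValueError("scale_sd must be > 0")
    d = (x - y) / scale_sd
    if covariate_diffs is not None:
        cov = np.atleast_2d(np.asarray(covariate_diffs, dtype=float))
        if cov.shape[0] != n:
            raise ValueError("covariate_diffs must have one row per pair")
        D = np.column_stack([d, cov])
    else:
        D = d[:, None]
    p = D.shape[1]
    informative = np.any(D != 0.0, axis=1)
    if not informative.any():
        raise SeparationError("all within-pair differences are zero")
    if np.all(d[informative] >= 0) and np.any(d > 0) and not np.any(d < 0):
        if covariate_diffs is None:
            raise SeparationError("all exposure differences are non-negative")
    if np.all(d[informative] <= 0) and np.any(d < 0) and not np.any(d > 0):
        if covariate_diffs is None:
            raise SeparationError("all exposure differences are non-positive")

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = D @ beta
        mu = expit(eta)
        grad = D.T @ (1.0 - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = (D * w[:, None]).T @ D
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        # Dampen very large steps to keep Newton stable far from optimum.
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.linalg.norm(beta) > 50.0:
            raise SeparationError("estimate diverged (monotone likelihood)")
    if not converged:
        eta = D @ beta
        mu = expit(eta)
        grad = D.T @ (1.0 - mu)
        if np.linalg.norm(grad) >= 1e-6:
            raise SeparationError("Newton iteration failed to converge")
    mu = expit(D @ beta)
    w = mu * (1.0 - mu)
    info = (D * w[:, None]).T @ D
    cov_model = np.linalg.inv(info)
    scores = D * (1.0 - mu)[:, None]
    cluster_idx = _pair_clusters(case_ids, control_ids, clusters, n)
    n_clusters = int(cluster_idx.max()) + 1
    summed = np.zeros((n_clusters, p))
    np.add.at(summed, cluster_idx, scores)
    B = summed.T @ summed
    cov_robust = cov_model @ B @ cov_model
    return ClogitResult(
        beta=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        n_pairs=n,
        n_clusters=n_clusters,
        converged=True,
    )


def _variable_delta(knee, variable: str, from_month: int, to_month: int):
    from . import metrics

    if variable in metrics.REGIONS:
        return metrics.interval_change(
            knee, metrics.REGIONS[variable], from_month, to_month
        ).delta
    if variable == "thinning_score":
        return metrics.thinning_thickening_scores(knee, from_month, to_month).thinning
    if variable == "thickening_score":
        return metrics.thinning_thickening_scores(knee, from_month, to_month).thickening
    if variable == "mjsw":
        return metrics.mjsw_change(knee, from_month, to_month)
    raise ValueError(f"unknown variable {variable!r}")


def _bmi_at(knee, month: int) -> Optional[float]:
    """BMI at the interval start, falling back to the latest earlier visit."""
    for m in sorted((v.visit_month for v in knee.pro_visits), reverse=True):
        if m <= month:
            v = knee.pro_at(m)
            if v is not None and v.present and v.bmi is not None:
                return v.bmi
    return None


def build_table(
    pairs,
    knees: Mapping[str, object],
    variables: Sequence[str],
    intervals: Sequence[tuple[int, int]],
    clusters: Optional[Mapping[str, str]] = None,
) -> list[PairedComparison]:
    """One unadjusted and one BMI-adjusted row per (variable, interval).

    Pairwise-complete: a pair enters a row only when both knees have a
    defined change for that variable and interval.  The conditional-
    logistic OR is per control-SD of that row's control changes and
    uses the cluster-robust sandwich variance.  Change variables enter
    the model in the *loss* direction (negated change), so OR > 1
    means greater structural deterioration among cases; the thickening
    score, a gain measure, enters on its raw scale.  Group means and
    SDs are always reported on the original scale (loss negative).
    Rows with fewer than two complete pairs, zero control SD, or a
    separated likelihood are emitted without the affected statistics
    (or skipped entirely when no paired test is possible).
    """
    rows: list[PairedComparison] = []
    for variable in variables:
        for from_month, to_month in intervals:
            rec = []
            for pair in pairs:
                ck = knees[pair.case_knee_id]
                kk = knees[pair.control_knee_id]
                dc = _variable_delta(ck, variable, from_month, to_month)
                dk = _variable_delta(kk, variable, from_month, to_month)
                if dc is None or dk is None:
                    continue
                rec.append((pair, ck, kk, dc, dk))
            if len(rec) < 2:
                continue
            case_vals = np.array([r[3] for r in rec])
            ctrl_vals = np.array([r[4] for r in rec])
            scale_sd = float(np.std(ctrl_vals, ddof=1))
            sign = 1.0 if variable == "thickening_score" else -1.0
            try:
                t, pt, _ = paired_t(case_vals, ctrl_vals)
            except ValueError:
                t = pt = None
            case_ids = [r[0].case_knee_id for r in rec]
            ctrl_ids = [r[0].control_knee_id for r in rec]
            for adjusted in (False, True):
                cov = None
                fit_case_vals, fit_ctrl_vals = case_vals, ctrl_vals
                fit_case_ids, fit_ctrl_ids = case_ids, ctrl_ids
                if adjusted:
                    keep, diffs = [], []
                    for i, (pair, ck, kk, _, _) in enumerate(rec):
                        bc, bk = _bmi_at(ck, from_month), _bmi_at(kk, from_month)
                        if bc is None or bk is None:
                            continue
                        keep.append(i)
                        diffs.append(bmi_adjustment_covariates(bc, bk))
                    if len(keep) < 2:
                        continue
                    cov = np.vstack(diffs)
                    # Constant-zero indicator differences carry no
                    # information and would make the fit singular.
                    nonzero = np.any(cov != 0.0, axis=0)
                    cov = cov[:, nonzero] if nonzero.any() else None
                    fit_case_vals = case_vals[keep]
                    fit_ctrl_vals = ctrl_vals[keep]
                    fit_case_ids = [case_ids[i] for i in keep]
                    fit_ctrl_ids = [ctrl_ids[i] for i in keep]
                beta = or_sd = lo = hi = None
                if scale_sd > 0:
                    try:
                        fit = clogit_1to1(
                            sign * fit_case_vals,
                            sign * fit_ctrl_vals,
                            scale_sd,
                            covariate_diffs=cov,
                            case_ids=fit_case_ids,
                            control_ids=fit_ctrl_ids,
                            clusters=clusters,
                        )
                        beta = fit.beta_exposure
                        or_sd = fit.or_per_sd
                        lo, hi = fit.ci95(robust=True)
                    except SeparationError:
                        pass
                rows.append(
                    PairedComparison(
                        variable=variable,
                        from_month=from_month,
                        to_month=to_month,
                        n_pairs=len(fit_case_vals) if adjusted else len(rec),
                        case_mean=float(np.mean(case_vals)),
                        case_sd=float(np.std(case_vals, ddof=1)),
                        control_mean=float(np.mean(ctrl_vals)),
                        control_sd=scale_sd,
                        t_stat=t,
                        t_pvalue=pt,
                        beta=beta,
                        or_per_sd=or_sd,
                        ci95_low=lo,
                        ci95_high=hi,
                        robust=True,
                        adjusted=adjusted,
                    )
                )
    return rows


@dataclass(frozen=True)
class MaintenanceRow:
    """Kruskal-Wallis comparison of maintained vs non-maintained cases."""

    variable: str
    from_month: int
    to_month: int
    n_maintained: int
    n_not_maintained: int
    mean_maintained: float
    sd_maintained: float
    mean_not_maintained: float
    sd_not_maintained: float
    h_stat: float
    p_value: float


def maintenance_table(
    case_knees_by_status: Mapping[str, Sequence[object]],
    variables: Sequence[str],
    interval: tuple[int, int],
) -> list[MaintenanceRow]:
    """Compare cartilage change between vKR+/+ and vKR+/- case knees."""
    from .classifier import MAINTAINED, NOT_MAINTAINED

    from_month, to_month = interval
    rows: list[MaintenanceRow] = []
    for variable in variables:
        groups: dict[str, list[float]] = {MAINTAINED: [], NOT_MAINTAINED: []}
        for status, knees in case_knees_by_status.items():
            for knee in knees:
                d = _variable_delta(knee, variable, from_month, to_month)
                if d is not None:
                    groups[status].append(d)
        gm, gn = groups[MAINTAINED], groups[NOT_MAINTAINED]
        if not gm or not gn or len(gm) + len(gn) < 3:
            continue
        h, p = kruskal_wallis(gm, gn)
        rows.append(
            MaintenanceRow(
                variable=variable,
                from_month=from_month,
                to_month=to_month,
                n_maintained=len(gm),
                n_not_maintained=len(gn),
                mean_maintained=float(np.mean(gm)),
                sd_maintained=float(np.std(gm, ddof=1)) if len(gm) > 1 else float("nan"),
                mean_not_maintained=float(np.mean(gn)),
                sd_not_maintained=float(np.std(gn, ddof=1)) if len(gn) > 1 else float("nan"),
                h_stat=h,
                p_value=p,
            )
        )
    return rows


def kruskal_wallis(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mid-rank Kruskal-Wallis H with tie correction, chi-square p (1 df).

    Two identical constant groups give (0, 1) rather than an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size + b.size < 3:
        raise ValueError("combined n must be >= 3")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(a, b)
    return float(h), float(p)
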