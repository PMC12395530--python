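"""End-to-end orchestration: generate -> classify -> select -> match ->
measure -> analyse, with CSV interchange and a per-knee audit log.

The interchange format is two CSV tables:

``knees.csv`` - one row per knee: participant_id, knee_id, side, sex,
    age_baseline, klg, jsn_medial, jsn_lateral, surgical_kr_month,
    continuous_coverage, is_progressor, latent_severity.  An empty klg
    marks a missing radiographic reading; derived stratum fields are
    recomputed on read.

``visits.csv`` - one row per knee-visit: knee_id, visit_month,
    pro_present, koos_pain, koos_qol, womac_pain, bmi, cart_readable,
    mjsw_medial, and 16 ``th_<subregion>`` thickness columns.
    ``pro_present``/``cart_readable`` are ''/0/1: empty means no record
    of that kind exists for the month, 0 a missed/unreadable visit.

Missing values are encoded as empty fields throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    MAINTAINED,
    NOT_MAINTAINED,
    MissingVisitError,
    VkrModelParams,
    evaluate_vkr,
    maintenance_status,
)
from .cohort import (
    MONTHS,
    CartilageVisit,
    KneeSeries,
    ProVisit,
    RadiographicBaseline,
    SimConfig,
    generate_cohort,
    inject_missingness,
)
from .metrics import SUBREGIONS
from .selection import (
    MatchedPair,
    apply_exclusion_cascade,
    match_pairs,
    select_cases,
    select_controls,
)
from .stats import build_table, maintenance_table

logger = logging.getLogger(__name__)

DEFAULT_VARIABLES = (
    "cMFTC",
    "MFTC",
    "cLFTC",
    "LFTC",
    "cMT",
    "ccMF",
    "thinning_score",
    "thickening_score",
    "mjsw",
)
#: Primary 2-year interval first, then the four annual descriptive ones,
#: all relative to a 60 M target (t0 = 48 M, so T-4..T0 = months 0..48).
DEFAULT_INTERVALS = ((24, 48), (0, 12), (12, 24), (24, 36), (36, 48))


class DataError(ValueError):
    """Malformed input data (schema violations, duplicate visits)."""


@dataclass
class RunConfig:
    mode: str = "synthetic"  # or "csv"
    sim: SimConfig = field(default_factory=SimConfig)
    params: VkrModelParams = field(default_factory=VkrModelParams)
    target_month: int = 60
    intervals: tuple[tuple[int, int], ...] = DEFAULT_INTERVALS
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    seed: int = 0
    output_dir: str = "vkr_run"
    visits_csv: Optional[str] = None
    knees_csv: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv":
            for name in ("visits_csv", "knees_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} must point to an existing file")
        t0 = self.target_month - 12
        for a, b in self.intervals:
            if not (0 <= a < b <= t0):
                raise ValueError(f"interval {(a, b)} outside the 0..{t0} scheme")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat YAML document into a RunConfig.

    Top-level keys mirror RunConfig; ``sim`` and ``params`` are nested
    mappings mirroring SimConfig and VkrModelParams.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**{**raw.get("sim", {})})
    params = VkrModelParams(**{**raw.get("params", {})})
    kwargs = {
        k: v for k, v in raw.items() if k not in ("sim", "params")
    }
    if "intervals" in kwargs:
        kwargs["intervals"] = tuple(tuple(iv) for iv in kwargs["intervals"])
    if "variables" in kwargs:
        kwargs["variables"] = tuple(kwargs["variables"])
    return RunConfig(sim=sim, params=params, **kwargs)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_TH_COLS = [f"th_{s}" for s in SUBREGIONS]
_VISIT_COLS = [
    "knee_id",
    "visit_month",
    "pro_present",
    "koos_pain",
    "koos_qol",
    "womac_pain",
    "bmi",
    "cart_readable",
    "mjsw_medial",
    *_TH_COLS,
]
_KNEE_COLS = [
    "participant_id",
    "knee_id",
    "side",
    "sex",
    "age_baseline",
    "klg",
    "jsn_medial",
    "jsn_lateral",
    "surgical_kr_month",
    "continuous_coverage",
    "is_progressor",
    "latent_severity",
]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_cohort_csv(
    cohort: Sequence[KneeSeries], visits_path: str | Path, knees_path: str | Path
) -> None:
    """Write the cohort losslessly to the two interchange tables."""
    knee_rows = []
    visit_rows = []
    for knee in cohort:
        r = knee.radiographic
        knee_rows.append(
            {
                "participant_id": knee.participant_id,
                "knee_id": knee.knee_id,
                "side": knee.side,
                "sex": knee.sex,
                "age_baseline": _fmt(knee.age_baseline),
                "klg": _fmt(r.klg if r else None),
                "jsn_medial": _fmt(r.jsn_medial if r else None),
                "jsn_lateral": _fmt(r.jsn_lateral if r else None),
                "surgical_kr_month": _fmt(knee.surgical_kr_month),
                "continuous_coverage": _fmt(knee.continuous_coverage),
                "is_progressor": _fmt(knee.is_progressor),
                "latent_severity": _fmt(knee.latent_severity),
            }
        )
        months = sorted(
            {v.visit_month for v in knee.pro_visits}
            | {v.visit_month for v in knee.cartilage_visits}
        )
        for m in months:
            pv = knee.pro_at(m)
            cv = knee.cart_at(m)
            row = {c: "" for c in _VISIT_COLS}
            row["knee_id"] = knee.knee_id
            row["visit_month"] = str(m)
            if pv is not None:
                row["pro_present"] = _fmt(pv.present)
                row["koos_pain"] = _fmt(pv.koos_pain)
                row["koos_qol"] = _fmt(pv.koos_qol)
                row["womac_pain"] = _fmt(pv.womac_pain)
                row["bmi"] = _fmt(pv.bmi)
            if cv is not None:
                row["cart_readable"] = _fmt(cv.readable)
                row["mjsw_medial"] = _fmt(cv.mjsw_medial)
                for s in SUBREGIONS:
                    row[f"th_{s}"] = _fmt(cv.thickness.get(s))
            visit_rows.append(row)
    pd.DataFrame(knee_rows, columns=_KNEE_COLS).to_csv(knees_path, index=False)
    pd.DataFrame(visit_rows, columns=_VISIT_COLS).to_csv(visits_path, index=False)


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def read_cohort_csv(
    visits_path: str | Path, knees_path: str | Path
) -> list[KneeSeries]:
    """Read the two interchange tables back into KneeSeries objects."""
    knees_df = pd.read_csv(knees_path, dtype=str, keep_default_na=False)
    visits_df = pd.read_csv(visits_path, dtype=str, keep_default_na=False)
    missing = set(_KNEE_COLS) - set(knees_df.columns)
    if missing:
        raise DataError(f"knees table missing columns: {sorted(missing)}")
    unknown_th = [
        c for c in visits_df.columns if c.startswith("th_") and c not in _TH_COLS
    ]
    if unknown_th:
        raise DataError(f"unknown subregion columns: {unknown_th}")
    missing = set(_VISIT_COLS) - set(visits_df.columns)
    if missing:
        raise DataError(f"visits table missing columns: {sorted(missing)}")
    dup = visits_df.duplicated(subset=["knee_id", "visit_month"], keep=False)
    if dup.any():
        first = visits_df[dup].iloc[0]
        raise DataError(
            f"duplicate visit row for knee {first['knee_id']} month "
            f"{first['visit_month']}"
        )
    visits_by_knee: dict[str, list[pd.Series]] = {}
    for _, row in visits_df.iterrows():
        visits_by_knee.setdefault(row["knee_id"], []).append(row)
    cohort: list[KneeSeries] = []
    for _, kr in knees_df.iterrows():
        radiographic = None
        if kr["klg"] != "":
            radiographic = RadiographicBaseline.from_grades(
                int(kr["klg"]), int(kr["jsn_medial"]), int(kr["jsn_lateral"])
            )
        pro_visits: list[ProVisit] = []
        cart_visits: list[CartilageVisit] = []
        for row in sorted(
            visits_by_knee.get(kr["knee_id"], []), key=lambda r: int(r["visit_month"])
        ):
            m = int(row["visit_month"])
            if row["pro_present"] != "":
                pro_visits.append(
                    ProVisit(
                        m,
                        _opt_float(row["koos_pain"]),
                        _opt_float(row["koos_qol"]),
                        _opt_float(row["womac_pain"]),
                        _opt_float(row["bmi"]),
                        present=row["pro_present"] == "1",
                    )
                )
            if row["cart_readable"] != "":
                readable = row["cart_readable"] == "1"
                thickness = {}
                if readable:
                    thickness = {s: float(row[f"th_{s}"]) for s in SUBREGIONS}
                cart_visits.append(
                    CartilageVisit(m, thickness, _opt_float(row["mjsw_medial"]), readable)
                )
        cohort.append(
            KneeSeries(
                participant_id=kr["participant_id"],
                knee_id=kr["knee_id"],
                side=kr["side"],
                sex=kr["sex"],
                age_baseline=float(kr["age_baseline"]),
                radiographic=radiographic,
                pro_visits=pro_visits,
                cartilage_visits=cart_visits,
                surgical_kr_month=(
                    int(float(kr["surgical_kr_month"]))
                    if kr["surgical_kr_month"] != ""
                    else None
                ),
                continuous_coverage=kr["continuous_coverage"] == "1",
                is_progressor=(
                    None if kr["is_progressor"] == "" else kr["is_progressor"] == "1"
                ),
                latent_severity=_opt_float(kr["latent_severity"]),
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write the run directory.

    Emits knees.csv/visits.csv (synthetic mode), cascade.csv,
    assessments.csv, pairs.csv, changes.csv, results.csv,
    maintenance.csv, run.log (one machine-readable exclusion reason per
    knee) and manifest.json.  Identical config yields identical output.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    if config.mode == "synthetic":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort = inject_missingness(generate_cohort(sim), sim)
        write_cohort_csv(cohort, outdir / "visits.csv", outdir / "knees.csv")
    else:
        cohort = read_cohort_csv(config.visits_csv, config.knees_csv)
    log_lines.append(f"cohort_size {len(cohort)}")

    # Stage 1: exclusion cascade.
    cascade = apply_exclusion_cascade(cohort, config.target_month)
    for knee_id, step in sorted(cascade.removed.items()):
        log_lines.append(f"excluded {step} {knee_id}")
    pd.DataFrame(
        [
            {"step": s.label, "n_removed": s.n_removed, "n_remaining": s.n_remaining}
            for s in cascade.steps
        ]
    ).to_csv(outdir / "cascade.csv", index=False)

    # Stage 2: remove surgical KRs from the vKR selection population.
    selection_pop = []
    for knee in cascade.eligible:
        if (
            knee.surgical_kr_month is not None
            and knee.surgical_kr_month <= config.target_month
        ):
            log_lines.append(f"excluded surgical_kr_by_target {knee.knee_id}")
        else:
            selection_pop.append(knee)
    log_lines.append(f"selection_population {len(selection_pop)}")

    # Stage 3: classify every knee-year for the audit table.
    assessments = []
    for knee in selection_pop:
        for t0 in MONTHS[1:-1]:
            a = evaluate_vkr(knee, t0, config.params)
            assessments.append(dataclasses.asdict(a))
    pd.DataFrame(assessments).to_csv(outdir / "assessments.csv", index=False)

    # Stage 4: case and control selection, matching.
    by_id = {k.knee_id: k for k in cohort}
    case_ids = select_cases(
        selection_pop, config.params, config.target_month, require_mri_through=config.target_month - 12
    )
    control_ids = select_controls(
        selection_pop, case_ids, config.params, config.target_month
    )
    log_lines.append(f"cases_selected {len(case_ids)}")
    log_lines.append(f"controls_selected {len(control_ids)}")
    pairs, unmatched = match_pairs(
        [by_id[i] for i in case_ids],
        [by_id[i] for i in control_ids],
        age_caliper=5.0,
        seed=config.seed,
    )
    for cid in unmatched:
        log_lines.append(f"unmatched_case {cid}")
    pd.DataFrame(
        [dataclasses.asdict(p) for p in pairs],
        columns=[f.name for f in dataclasses.fields(MatchedPair)],
    ).to_csv(outdir / "pairs.csv", index=False)

    # Stage 5: interval changes for every matched knee.
    from .stats import _variable_delta  # internal reuse for the audit table

    change_rows = []
    for p in pairs:
        for role, kid in (("case", p.case_knee_id), ("control", p.control_knee_id)):
            for variable in config.variables:
                for a, b in config.intervals:
                    d = _variable_delta(by_id[kid], variable, a, b)
                    change_rows.append(
                        {
                            "knee_id": kid,
                            "role": role,
                            "variable": variable,
                            "from_month": a,
                            "to_month": b,
                            "delta_um": "" if d is None else d,
                        }
                    )
    pd.DataFrame(
        change_rows,
        columns=["knee_id", "role", "variable", "from_month", "to_month", "delta_um"],
    ).to_csv(outdir / "changes.csv", index=False)

    # Stage 6: matched-pair statistics.
    clusters = {k.knee_id: k.participant_id for k in cohort}
    results = build_table(
        pairs, by_id, config.variables, config.intervals, clusters
    )
    result_cols = [
        "variable",
        "from_month",
        "to_month",
        "n_pairs",
        "case_mean",
        "case_sd",
        "control_mean",
        "control_sd",
        "t_stat",
        "t_pvalue",
        "beta",
        "or_per_sd",
        "ci95_low",
        "ci95_high",
        "robust",
        "adjusted",
    ]
    pd.DataFrame(
        [dataclasses.asdict(r) for r in results], columns=result_cols
    ).to_csv(outdir / "results.csv", index=False)
    if not pairs:
        logger.warning("no vKR cases could be matched; results.csv is empty")

    # Stage 7: 72 M maintenance split and sensitivity comparison.
    by_status: dict[str, list[KneeSeries]] = {MAINTAINED: [], NOT_MAINTAINED: []}
    matched_case_ids = [p.case_knee_id for p in pairs]
    for cid in matched_case_ids:
        try:
            status = maintenance_status(by_id[cid], config.params)
        except MissingVisitError:
            log_lines.append(f"maintenance_undetermined missing_72m {cid}")
            continue
        by_status[status].append(by_id[cid])
    log_lines.append(
        f"maintenance_split {len(by_status[MAINTAINED])}"
        f" {len(by_status[NOT_MAINTAINED])}"
    )
    m_rows = maintenance_table(
        by_status, [v for v in config.variables if v != "mjsw"], config.intervals[0]
    )
    pd.DataFrame([dataclasses.asdict(r) for r in m_rows]).to_csv(
        outdir / "maintenance.csv", index=False
    )

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    cfg = _config_dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "vkrpipe_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_pairs": len(pairs),
        "n_unmatched_cases": len(unmatched),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
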