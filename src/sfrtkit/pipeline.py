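"""Association analysis between arm dosimetry and treatment response.

Orchestrates the study's statistical scan: QC filtering on the measured
treated-area fraction, the day-17 snapshot (per-arm survival proportion and
net body-weight change), the arm-level survival regression scan, the
per-animal univariate Cox scan, the per-animal body-weight regression scan,
and the Pearson cross-correlation matrix of the dosimetric parameters.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort
from .design import TUMOR_PARAMETERS, study_arm_table
from .stats import (
    cox_fit_univariate,
    ols_univariate,
    pearson_corr,
    significance_stars,
)

__all__ = [
    "Day17Snapshot",
    "QCReport",
    "qc_filter",
    "day_snapshot",
    "survival_regression_scan",
    "coxph_scan",
    "bodyweight_regression_scan",
    "correlation_matrix",
    "report",
]

#: parameters scanned against body weight: tissue (normal) EUD replaces
#: tumour EUD in the toxicity analysis
WEIGHT_PARAMETERS = [
    "valley_dose",
    "valley_width",
    "peak_width",
    "pct_volume_irradiated",
    "pvdr",
    "vol_avg_dose",
    "normal_eud",
    "peak_dose",
]


@dataclass(frozen=True)
class QCReport:
    excluded: Dict[str, Tuple[float, float]]  # id -> (measured %, nominal %)
    missing: Tuple[str, ...] = ()
    tolerance: float = 5.0


@dataclass(frozen=True)
class Day17Snapshot:
    day: int
    pct_survival: Dict[str, float]  # per arm, alive/initial * 100
    mean_net_weight_change: Dict[str, float]  # fraction of baseline net weight
    n_alive: Dict[str, int]
    animal_weight_change: pd.DataFrame  # per-animal rows (animal_id, arm, change)


def qc_filter(
    cohort: Cohort,
    measured_area_fraction: Dict[str, float],
    tolerance: float = 5.0,
) -> Tuple[Cohort, QCReport]:
    """Exclude animals whose measured treated-area fraction deviates from the
    arm's nominal percentage volume irradiated by more than ``tolerance``
    percentage points (strict inequality; a deviation of exactly 5.0 is
    retained).  Animals without a measurement are retained and reported.
    """
    table = study_arm_table()
    excluded: Dict[str, Tuple[float, float]] = {}
    missing: List[str] = []
    kept = []
    for rec in cohort.records:
        nominal = float(table.loc[rec.arm, "pct_volume_irradiated"])
        measured = measured_area_fraction.get(rec.animal_id)
        if measured is None:
            missing.append(rec.animal_id)
            kept.append(rec)
            continue
        if not 0.0 <= measured <= 100.0:
            raise ValueError(f"measured fraction out of [0, 100] for {rec.animal_id}")
        if abs(measured - nominal) > tolerance:
            excluded[rec.animal_id] = (measured, nominal)
        else:
            kept.append(rec)
    filtered = Cohort(records=kept, config=cohort.config, ground_truth=cohort.ground_truth)
    return filtered, QCReport(excluded=excluded, missing=tuple(missing), tolerance=tolerance)


def day_snapshot(cohort: Cohort, day: Optional[int] = None, tumor_density: float = 1.0) -> Day17Snapshot:
    """Per-arm survival proportion and net body-weight change at a snapshot day.

    Net weight = measured weight - tumour_volume * density (mm^3 -> g at
    1 g/cm^3); the change is relative to the animal's pre-treatment net
    weight, using the last visit at or before the snapshot day.  Survival is
    the simple proportion of the initial arm size still on study past the
    snapshot day.
    """
    if day is None:
        day = cohort.config.snapshot_day
    if day > cohort.config.follow_up:
        raise ValueError("snapshot day beyond follow-up")
    arms = [a for a, _ in cohort.config.arms]
    n_init = {a: 0 for a in arms}
    n_alive = {a: 0 for a in arms}
    rows = []
    for rec in cohort.records:
        n_init[rec.arm] += 1
        alive = rec.event == 0 or rec.event_time > day
        if not alive:
            continue
        n_alive[rec.arm] += 1
        upto = [v for v in rec.visits if v[0] <= day]
        if not upto:
            raise ValueError(f"no visit at or before day {day} for {rec.animal_id}")
        d0, v0, w0 = rec.visits[0]
        dd, vv, ww = upto[-1]
        net0 = w0 - v0 * tumor_density / 1000.0
        net = ww - vv * tumor_density / 1000.0
        rows.append(
            dict(animal_id=rec.animal_id, arm=rec.arm,
                 net_weight_change=(net - net0) / net0, visit_day=dd)
        )
    per_animal = pd.DataFrame(rows, columns=["animal_id", "arm", "net_weight_change", "visit_day"])
    pct = {a: 100.0 * n_alive[a] / n_init[a] for a in arms if n_init[a] > 0}
    mean_change = {
        a: float(per_animal.loc[per_animal["arm"] == a, "net_weight_change"].mean())
        if n_alive[a] > 0
        else math.nan
        for a in arms
    }
    return Day17Snapshot(
        day=day,
        pct_survival=pct,
        mean_net_weight_change=mean_change,
        n_alive=n_alive,
        animal_weight_change=per_animal,
    )


def _scan_row(parameter: str, fit) -> dict:
    return dict(
        parameter=parameter,
        estimate=fit.slope_,
        se=fit.se_slope_,
        t=fit.t_,
        f=fit.f_,
        r_squared=fit.r_squared_,
        p=fit.p_value_,
        stars=significance_stars(fit.p_value_),
        n=fit.n_,
    )


def survival_regression_scan(
    arm_table: pd.DataFrame,
    pct_survival: Dict[str, float],
    parameters: Sequence[str] = tuple(TUMOR_PARAMETERS),
) -> pd.DataFrame:
    """Arm-level univariate OLS of day-17 survival % on each dosimetric
    parameter.  The untreated arm (all-zero dosimetry) enters every fit
    except PVDR, where it is undefined.
    """
    rows = []
    for p in parameters:
        sub = arm_table.loc[arm_table.index.isin(pct_survival)]
        x = sub[p].astype(float)
        keep = ~x.isna()
        x = x[keep]
        y = np.array([pct_survival[a] for a in x.index])
        if x.nunique() < 2:
            raise ValueError(f"parameter {p!r} is constant across arms")
        rows.append(_scan_row(p, ols_univariate(x.to_numpy(), y)))
    return pd.DataFrame(rows)


def coxph_scan(
    cohort: Cohort,
    arm_table: Optional[pd.DataFrame] = None,
    parameters: Sequence[str] = tuple(TUMOR_PARAMETERS),
    ties: str = "breslow",
) -> pd.DataFrame:
    """Univariate Cox proportional-hazards scan over the dosimetric
    parameters; each animal inherits its arm's parameter value.  Rows are
    sorted by |z| descending.  Animals whose arm has an undefined parameter
    (PVDR in the untreated arm) drop out of that row's fit.
    """
    if arm_table is None:
        arm_table = study_arm_table()
    time = np.array([r.event_time for r in cohort.records], dtype=float)
    event = np.array([r.event for r in cohort.records], dtype=int)
    arm_of = np.array([r.arm for r in cohort.records])
    rows = []
    for p in parameters:
        x = np.array([arm_table.loc[a, p] for a in arm_of], dtype=float)
        keep = ~np.isnan(x)
        fit = cox_fit_univariate(time[keep], event[keep], x[keep], ties=ties)
        rows.append(
            dict(
                parameter=p,
                estimate=fit.coef_,
                se=fit.se_,
                hazard_ratio=fit.hazard_ratio_,
                ci_low=fit.conf_int_[0],
                ci_high=fit.conf_int_[1],
                z=fit.z_,
                p=fit.p_value_,
                stars=significance_stars(fit.p_value_),
                n=fit.n_subjects_,
                n_events=fit.n_events_,
            )
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["z"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def bodyweight_regression_scan(
    snapshot: Day17Snapshot,
    arm_table: Optional[pd.DataFrame] = None,
    parameters: Sequence[str] = tuple(WEIGHT_PARAMETERS),
) -> pd.DataFrame:
    """Per-animal univariate OLS of day-17 net body-weight change on each
    dosimetric parameter (tissue EUD replaces tumour EUD in this scan)."""
    if arm_table is None:
        arm_table = study_arm_table()
    df = snapshot.animal_weight_change
    if len(df) < 3:
        raise ValueError("need at least three animals alive at the snapshot day")
    rows = []
    for p in parameters:
        x = np.array([arm_table.loc[a, p] for a in df["arm"]], dtype=float)
        y = df["net_weight_change"].to_numpy()
        keep = ~np.isnan(x)
        rows.append(_scan_row(p, ols_univariate(x[keep], y[keep])))
    return pd.DataFrame(rows)


def correlation_matrix(
    arm_table: Optional[pd.DataFrame] = None,
    parameters: Sequence[str] = (
        "valley_dose", "peak_dose", "vol_avg_dose", "normal_eud", "tumor_eud",
        "peak_width", "valley_width", "pvdr", "pct_volume_irradiated",
    ),
    treated_only: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson correlations of the dosimetric parameters across
    arms (treated arms only by default, where PVDR is defined)."""
    if arm_table is None:
        arm_table = study_arm_table()
    sub = arm_table
    if treated_only:
        sub = sub.loc[sub["peak_dose"] > 0]
    if len(sub) < 3:
        raise ValueError("need at least three arms")
    k = len(parameters)
    out = pd.DataFrame(np.full((k, k), np.nan), index=parameters, columns=parameters)
    for i, a in enumerate(parameters):
        for j, b in enumerate(parameters[: i + 1]):
            out.iloc[i, j] = pearson_corr(sub[a].to_numpy(), sub[b].to_numpy())
    return out


def report(
    outdir,
    tables: Dict[str, pd.DataFrame],
    metadata: Optional[dict] = None,
    include_timestamp: bool = False,
) -> Path:
    """Write the analysis bundle: one CSV per table plus a JSON metadata
    block (seed, config digest; timestamp suppressed by default so repeated
    runs are byte-identical)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    digest_src = json.dumps(
        {k: v.round(12).to_json() for k, v in sorted(tables.items())}, sort_keys=True
    )
    meta["config_digest"] = hashlib.sha256(digest_src.encode()).hexdigest()[:16]
    if include_timestamp:
        import datetime

        meta["written_at"] = datetime.datetime.now().isoformat()
    for name, df in tables.items():
        keep_index = not df.index.equals(pd.RangeIndex(len(df)))
        df.to_csv(outdir / f"{name}.csv", index=keep_index)
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return outdir
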