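"""File formats: cohort CSV, beam-pattern configs, profile exports.

The cohort CSV is long-format, one row per animal-visit, with units fixed in
the column names (mm^3, g, days).  A ``schema_map`` lets differently-named
dialects (e.g. a supplementary data export) be read by declaring how their
headers map onto the canonical columns.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import AnimalRecord, Cohort, CohortConfig
from .dose import BeamPattern, DepthDoseModel, calibrate_mu

__all__ = [
    "COHORT_COLUMNS",
    "ellipsoid_volume",
    "write_cohort",
    "read_cohort",
    "pattern_from_config",
    "export_profile_csv",
]

COHORT_COLUMNS = [
    "animal_id",
    "arm",
    "day",
    "tumor_volume_mm3",
    "body_weight_g",
    "event_time_days",
    "event",
]


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Tumour volume from caliper half-lengths: V = (4/3) pi a b c (mm^3)."""
    if min(a, b, c) <= 0:
        raise ValueError("half-lengths must be > 0")
    return 4.0 / 3.0 * math.pi * a * b * c


def write_cohort(cohort: Cohort, path) -> Path:
    """Serialize a cohort to the long-format CSV (deterministic bytes)."""
    path = Path(path)
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    return path


def read_cohort(path, schema_map: Optional[Dict[str, str]] = None) -> Cohort:
    """Read and validate a cohort CSV.

    ``schema_map`` maps canonical column names to the file's header names.
    Unknown columns are preserved in the per-record metadata; missing
    mandatory columns, duplicate (animal_id, day) pairs and malformed
    numerics are hard errors reported with row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema_map:
        rename = {src: dst for dst, src in schema_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")

    for col in ("day", "tumor_volume_mm3", "body_weight_g", "event_time_days", "event"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"{path.name}: malformed {col} at file row(s) {rows}")
        df[col] = coerced
    dup = df.duplicated(subset=["animal_id", "day"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path.name}: duplicate (animal_id, day) at row(s) {rows}")
    neg = df["tumor_volume_mm3"] < 0
    if neg.any():
        rows = (df.index[neg] + 2).tolist()
        raise ValueError(f"{path.name}: negative tumor volume at row(s) {rows}")
    if not df["event"].isin((0, 1)).all():
        raise ValueError(f"{path.name}: event must be 0 or 1")
    const = df.groupby("animal_id")["event_time_days"].nunique()
    varying = const[const > 1].index.tolist()
    if varying:
        raise ValueError(f"{path.name}: event_time varies within animal(s) {varying}")

    records = []
    arm_counts: Dict[str, int] = {}
    for aid, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("day")
        arm = str(sub["arm"].iloc[0])
        arm_counts[arm] = arm_counts.get(arm, 0) + 1
        visits = [
            (int(r.day), float(r.tumor_volume_mm3), float(r.body_weight_g))
            for r in sub.itertuples()
        ]
        records.append(
            AnimalRecord(
                animal_id=str(aid),
                arm=arm,
                bin_index=-1,
                pre_treatment_volume=visits[0][1],
                visits=visits,
                event_time=float(sub["event_time_days"].iloc[0]),
                event=int(sub["event"].iloc[0]),
                cause="unknown",
            )
        )
    days = sorted(df["day"].unique())
    interval = int(np.min(np.diff(days))) if len(days) > 1 else 3
    config = CohortConfig(
        arms=tuple(arm_counts.items()),
        follow_up=int(max(df["event_time_days"].max(), df["day"].max())),
        visit_interval=max(interval, 1),
        snapshot_day=17,
    )
    return Cohort(records=records, config=config, ground_truth={"source": str(path)})


def pattern_from_config(path) -> tuple[BeamPattern, DepthDoseModel]:
    """Load a beam pattern from a YAML config with keys mirroring the
    dosimetric table column names (units Gy/mm).  Unknown keys are errors."""
    data = yaml.safe_load(Path(path).read_text())
    allowed = {
        "kind",
        "peak_surface_dose_gy",
        "valley_surface_dose_gy",
        "peak_width_mm",
        "valley_width_mm",
        "penumbra_width_mm",
        "field_extent_mm",
        "phase_mm",
        "mu_per_mm",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    pattern = BeamPattern(
        kind=data["kind"],
        peak_dose_surface=float(data["peak_surface_dose_gy"]),
        valley_dose_surface=float(data["valley_surface_dose_gy"]),
        peak_width=float(data["peak_width_mm"]),
        valley_width=float(data["valley_width_mm"]),
        penumbra_width=float(data.get("penumbra_width_mm", 0.0)),
        field_extent=float(data.get("field_extent_mm", 20.0)),
        phase=float(data.get("phase_mm", 0.0)),
    )
    mu = float(data["mu_per_mm"]) if "mu_per_mm" in data else calibrate_mu()
    return pattern, DepthDoseModel(mu=mu)


def export_profile_csv(path, positions_mm, dose_gy, header=("position_mm", "dose_Gy")) -> Path:
    """Two-column CSV export for lateral profiles and depth-dose curves."""
    path = Path(path)
    df = pd.DataFrame({header[0]: positions_mm, header[1]: dose_gy})
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    return path


def export_grid(path_prefix, grid) -> tuple[Path, Path]:
    """Flat binary dump of a dose grid plus a JSON sidecar recording shape,
    voxel size and axis order (x across peaks, y along peaks, z depth)."""
    prefix = Path(path_prefix)
    raw = prefix.with_suffix(".f32")
    grid.values.astype(np.float32).tofile(raw)
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            dict(
                shape=list(grid.values.shape),
                dtype="float32",
                voxel_size_mm=list(grid.voxel_size),
                origin_mm=list(grid.origin),
                axis_order=["x_across_peaks", "y_along_peaks", "z_depth"],
            ),
            indent=2,
        )
        + "\n"
    )
    return raw, sidecar
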