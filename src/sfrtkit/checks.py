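"""Reproduction checks against the published study values.

Each check recomputes a printed quantity from the package's own code and the
published design inputs (the six-arm dosimetric table, the per-arm
pre-treatment volumes, the reported model coefficients) and compares it with
the published number at its printed precision.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

from .cohort import CohortConfig, emit_cohort
from .design import mean_pretreatment_volume, study_arm_table
from .dose import DepthDoseModel, arm_preset, compose_grid
from .metrics import pvdr, volume_average_dose
from .stats import f_stat_from_r_squared, pearson_corr

__all__ = ["run_checks", "PUBLISHED"]

#: published reference values and the tolerance implied by their printed
#: precision, keyed by check name
PUBLISHED: Dict[str, tuple] = {
    "pvdr_half_field": (12.6, 0.05),
    "pvdr_2mm_array": (5.6, 0.05),
    "pvdr_uniform": (1.0, 0.05),
    "mean_pretreatment_volume_mm3": (566.0, 0.5),
    "f_stat_tumor_eud": (15.26, 0.005),
    "f_stat_valley_dose": (12.92, 0.005),
    "f_stat_pct_volume_irradiated": (10.05, 0.005),
    "f_stat_pvdr": (7.691, 0.0005),
    "corr_peak_width_valley_width": (1.00, 0.005),
    "corr_valley_dose_tumor_eud": (0.99, 0.005),
    "hazard_ratio_valley_dose": (0.81, 0.005),
    "hazard_change_pct_valley_dose": (19.0, 0.5),
    "uniform_volume_average_dose_gy": (20.0, 0.1),
    "cohort_size": (42, 0.5),
}


def run_checks(seed: int = 0) -> Dict[str, dict]:
    """Recompute every published-value check; returns
    ``{name: {"value": float, "n": int, "published": float, "pass": bool}}``.
    """
    table = study_arm_table()
    out: Dict[str, dict] = {}

    def add(name: str, value: float, n: int) -> None:
        ref, tol = PUBLISHED[name]
        out[name] = {
            "value": value,
            "n": n,
            "published": ref,
            "pass": bool(abs(value - ref) <= tol),
        }

    # PVDR arithmetic from the published surface doses, at table rounding
    add("pvdr_half_field", round(pvdr(39.0, 3.1), 1), 1)
    add("pvdr_2mm_array", round(pvdr(34.5, 6.2), 1), 1)
    add("pvdr_uniform", round(pvdr(20.8, 20.8), 1), 1)

    # mean of the six published per-arm pre-treatment volumes
    add("mean_pretreatment_volume_mm3", round(mean_pretreatment_volume(), 1), 6)

    # F statistics implied by the published R^2 values under the six-arm
    # (five for PVDR) univariate regression design
    add("f_stat_tumor_eud", round(f_stat_from_r_squared(0.7923, 6), 2), 6)
    add("f_stat_valley_dose", round(f_stat_from_r_squared(0.7636, 6), 2), 6)
    add("f_stat_pct_volume_irradiated", round(f_stat_from_r_squared(0.7153, 6), 2), 6)
    add("f_stat_pvdr", round(f_stat_from_r_squared(0.7194, 5), 3), 5)

    # Pearson correlations across the treated arms of the published table
    treated = table.loc[table["peak_dose"] > 0]
    add(
        "corr_peak_width_valley_width",
        round(pearson_corr(treated["peak_width"], treated["valley_width"]), 2),
        len(treated),
    )
    add(
        "corr_valley_dose_tumor_eud",
        round(pearson_corr(treated["valley_dose"], treated["tumor_eud"]), 2),
        len(treated),
    )

    # hazard-ratio consistency of the published valley-dose Cox coefficient
    beta_valley = -0.20947
    hr = math.exp(beta_valley)
    add("hazard_ratio_valley_dose", round(hr, 2), 42)
    add("hazard_change_pct_valley_dose", round((1.0 - hr) * 100.0, 1), 42)

    # dose-model closure: open-field volume average over 1 cm depth
    pattern, depth, _ = arm_preset("20GyUniformRT")
    grid = compose_grid(pattern, depth, extent=(20.0, 4.0, 10.0),
                        resolution=(0.05, 1.0, 0.05))
    add("uniform_volume_average_dose_gy", round(volume_average_dose(grid), 2), grid.values.size)

    # generator closure: the default six-arm cohort has 42 animals
    cohort = emit_cohort(CohortConfig(seed=seed))
    add("cohort_size", float(len(cohort)), len(cohort))

    return out
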