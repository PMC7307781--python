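"""Published six-arm study design constants.

The film-measured dosimetric summary of the six treatment arms, the per-arm
animal counts and the per-arm mean pre-treatment tumour volumes are design
inputs for the cohort generator and for the reproduction checks.  Values are
the published ones (surface doses in Gy, widths in mm, EUDs in Gy,
percentage volume irradiated in %); the dose model reproduces the
construction-anchored entries (peak/valley doses, widths) exactly and the
measurement-derived entries (EUDs, %volume of the non-uniform arms) only
approximately, so the measured table is kept verbatim here.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "study_arm_table",
    "mean_pretreatment_volume",
    "PRETREATMENT_VOLUMES_MM3",
    "DAY17_SURVIVORS",
    "TUMOR_PARAMETERS",
]

# columns: n animals, volume-average dose (Gy, within 1 cm depth), surface
# peak/valley dose (Gy), tumour/normal-tissue EUD (Gy), PVDR, valley/peak
# width (mm), % volume directly irradiated.  PVDR is undefined (NaN) for the
# untreated arm; the 50GySFRT collimator entries repeat the 20GySFRT
# geometry (same collimator, 2.5x output).
_ROWS = {
    # arm:            n  avg   peak  valley t_eud n_eud  pvdr  vw    pw    pct
    "Untreated":     (8,  0.0,   0.0,  0.0,  0.0,   0.0, math.nan, 0.0, 0.0,   0.0),
    "20GyUniformRT": (8, 20.0,  20.8, 20.8, 19.9,  20.1,  1.0, 20.0, 20.0, 100.0),
    "20GyHalfSFRT":  (5, 20.0,  39.0,  3.1,  2.9,  30.5, 12.6, 10.0, 10.0,  47.8),
    "20Gy2mmSFRT":   (6, 17.6,  34.5,  6.2,  5.2,  25.1,  5.6,  2.0,  2.2,  51.5),
    "20GySFRT":      (9, 20.0,  91.0,  6.8,  5.3,  47.4, 13.3,  0.9,  0.31,  20.3),
    "50GySFRT":      (6, 50.0, 225.0, 16.8, 13.1, 117.3, 13.4,  0.9,  0.31,  20.3),
}

_COLUMNS = [
    "n_animals",
    "vol_avg_dose",
    "peak_dose",
    "valley_dose",
    "tumor_eud",
    "normal_eud",
    "pvdr",
    "valley_width",
    "peak_width",
    "pct_volume_irradiated",
]

#: the eight dosimetric parameters scanned against tumour response
TUMOR_PARAMETERS = [
    "valley_dose",
    "tumor_eud",
    "pct_volume_irradiated",
    "pvdr",
    "peak_width",
    "valley_width",
    "vol_avg_dose",
    "peak_dose",
]

#: mean pre-treatment tumour volume per arm on treatment day (mm^3)
PRETREATMENT_VOLUMES_MM3 = {
    "Untreated": 511.84,
    "20GyUniformRT": 602.73,
    "20GyHalfSFRT": 608.77,
    "20Gy2mmSFRT": 489.2,
    "20GySFRT": 599.81,
    "50GySFRT": 584.06,
}

#: animals alive at the day-17 snapshot, per arm (reference outcome used by
#: the end-to-end arm-level regression demo)
DAY17_SURVIVORS = {
    "Untreated": 0,
    "20GyUniformRT": 8,
    "20GyHalfSFRT": 3,
    "20Gy2mmSFRT": 4,
    "20GySFRT": 4,
    "50GySFRT": 5,
}


def study_arm_table() -> pd.DataFrame:
    """Published dosimetric summary as a DataFrame indexed by arm name."""
    return pd.DataFrame.from_dict(_ROWS, orient="index", columns=_COLUMNS)


def mean_pretreatment_volume() -> float:
    """Across-arm mean of the per-arm pre-treatment volumes (mm^3)."""
    vols = PRETREATMENT_VOLUMES_MM3.values()
    return sum(vols) / len(vols)


def published_arm_dosimetry(name: str):
    """Published (film-measured) nine-parameter record for one arm.

    These are the study conditions the cohort generator and association
    scans run under; the parametric dose model's :func:`~sfrtkit.metrics.
    summarize_arm` provides the modelled counterpart.
    """
    from .metrics import ArmDosimetry  # local import avoids a cycle at import time

    table = study_arm_table()
    if name not in table.index:
        raise ValueError(f"unknown arm {name!r}")
    row = table.loc[name]
    return ArmDosimetry(
        arm=name,
        vol_avg_dose=float(row["vol_avg_dose"]),
        peak_dose=float(row["peak_dose"]),
        valley_dose=float(row["valley_dose"]),
        tumor_eud=float(row["tumor_eud"]),
        normal_eud=float(row["normal_eud"]),
        pvdr=None if math.isnan(row["pvdr"]) else float(row["pvdr"]),
        peak_width=float(row["peak_width"]),
        valley_width=float(row["valley_width"]),
        pct_volume_irradiated=float(row["pct_volume_irradiated"]),
    )
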