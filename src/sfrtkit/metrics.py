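"""The nine dosimetric parameters of a spatially fractionated field.

Peak/valley surface doses and widths read back the beam pattern; the
volume-average dose, tumour EUD (a = -10, 1 cm sphere at 5 mm depth) and
normal-tissue EUD (a = 5, concentric 2 cm sphere clipped to the dose grid)
are volumetric power-mean summaries; PVDR is peak/valley; the percentage of
the tumour cross-section directly irradiated is a purely geometric disk
coverage (with min/max positional averaging for the 2 mm arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .dose import (
    BeamPattern,
    DepthDoseModel,
    DoseGrid,
    arm_preset,
    depth_curve,
    lateral_profile,
)

__all__ = [
    "EUDParams",
    "ArmDosimetry",
    "eud",
    "pvdr",
    "volume_average_dose",
    "percent_volume_irradiated",
    "widths_from_profile",
    "sphere_mask",
    "summarize_arm",
]


@dataclass(frozen=True)
class EUDParams:
    """Equivalent-uniform-dose settings.

    ``a_tumor`` (large negative, pulls the power mean toward cold spots) and
    ``a_normal`` (positive, up-weights hot spots) are the tissue-specific
    exponents; the tumour region is a 1 cm diameter sphere centred at 5 mm
    depth and the normal-tissue region a concentric 2 cm sphere clipped to
    the grid.
    """

    a_tumor: float = -10.0
    a_normal: float = 5.0
    tumor_diameter: float = 10.0
    tumor_center_depth: float = 5.0
    normal_diameter: float = 20.0

    def __post_init__(self) -> None:
        if not (self.a_tumor < 0 < self.a_normal):
            raise ValueError("require a_tumor < 0 < a_normal")
        if min(self.tumor_diameter, self.normal_diameter) <= 0:
            raise ValueError("region diameters must be > 0")


@dataclass(frozen=True)
class ArmDosimetry:
    """The nine dosimetric parameters of one treatment arm."""

    arm: str
    vol_avg_dose: float
    peak_dose: float
    valley_dose: float
    tumor_eud: float
    normal_eud: float
    pvdr: Optional[float]  # None where undefined (untreated arm)
    peak_width: float
    valley_width: float
    pct_volume_irradiated: float
    pct_volume_min: float = math.nan
    pct_volume_max: float = math.nan

    def as_dict(self) -> dict:
        d = {
            "arm": self.arm,
            "vol_avg_dose": self.vol_avg_dose,
            "peak_dose": self.peak_dose,
            "valley_dose": self.valley_dose,
            "tumor_eud": self.tumor_eud,
            "normal_eud": self.normal_eud,
            "pvdr": math.nan if self.pvdr is None else self.pvdr,
            "peak_width": self.peak_width,
            "valley_width": self.valley_width,
            "pct_volume_irradiated": self.pct_volume_irradiated,
            "pct_volume_min": self.pct_volume_min,
            "pct_volume_max": self.pct_volume_max,
        }
        return d


def eud(doses, a: float, weights=None) -> float:
    """Generalized (power) mean dose ``(sum w_i D_i^a / sum w_i)**(1/a)``.

    For a < 0 any zero-dose voxel drives the mean to its limit, 0.  ``a = 0``
    (geometric mean) is not part of this model and is rejected.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose region")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if a == 0:
        raise ValueError("a = 0 is undefined in this EUD model")
    if weights is None:
        weights = np.ones_like(doses)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != doses.shape:
            raise ValueError("weights must match doses")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    if a < 0 and np.any((doses == 0) & (weights > 0)):
        return 0.0
    # normalize by the max for numerical stability at extreme exponents
    scale = doses.max()
    if scale == 0.0:
        return 0.0
    rel = doses / scale
    m = np.average(rel**a, weights=weights)
    return float(scale * m ** (1.0 / a))


def pvdr(peak_dose: float, valley_dose: float) -> float:
    """Peak-to-valley dose ratio.  Undefined for a non-positive valley."""
    if valley_dose <= 0:
        raise ValueError("PVDR undefined for valley dose <= 0")
    return peak_dose / valley_dose


def volume_average_dose(grid: DoseGrid, depth_limit: float = 10.0) -> float:
    """Arithmetic mean dose of all voxels with centre depth < depth_limit."""
    z = grid.z
    sel = z < depth_limit
    if not sel.any():
        raise ValueError("depth_limit excludes the whole grid")
    if depth_limit > z[-1] + grid.voxel_size[2] + 1e-12:
        raise ValueError("depth_limit exceeds the grid depth")
    return float(grid.values[:, :, sel].mean())


def _disk_coverage(pattern: BeamPattern, diameter: float, phase: float) -> float:
    """Fraction (%) of a surface disk of given diameter lying inside peak
    apertures, for an array shifted laterally by ``phase``."""
    r = diameter / 2.0
    if pattern.kind == "uniform":
        return 100.0 if pattern.peak_dose_surface > 0 else 0.0
    if pattern.kind == "half_field":
        # aperture is the half-plane x <= 0; disk centred on the boundary
        return 50.0
    # planar array: integrate chord length over aperture stripes
    n = 4001
    x = np.linspace(-r, r, n)
    chord = 2.0 * np.sqrt(np.maximum(r**2 - x**2, 0.0))
    p = pattern.period
    xm = np.mod(x - pattern.phase - phase + p / 2.0, p) - p / 2.0
    inside = (np.abs(xm) <= pattern.peak_width / 2.0).astype(float)
    area_in = np.trapezoid(chord * inside, x)
    area = math.pi * r**2
    return float(100.0 * area_in / area)


def percent_volume_irradiated(
    pattern: BeamPattern,
    tumor_diameter: float = 10.0,
    phase_offsets: Optional[Sequence[float]] = None,
) -> Tuple[float, float, float]:
    """Percentage of the tumour cross-section directly irradiated.

    Returns ``(mean, min, max)`` over the supplied phase offsets.  By
    default the two extreme tumour positions under the array are used: the
    maximum-coverage phase and the minimum-coverage phase, found by scanning
    one period (for the 2 mm array these are the "at most three peaks" and
    "at minimum two peaks" positions).
    """
    if tumor_diameter <= 0:
        raise ValueError("tumor_diameter must be > 0")
    if pattern.kind != "planar_array":
        c = _disk_coverage(pattern, tumor_diameter, 0.0)
        return c, c, c
    if phase_offsets is None:
        scan = np.linspace(0.0, pattern.period, 101)
        cov = [_disk_coverage(pattern, tumor_diameter, ph) for ph in scan]
        phase_offsets = [scan[int(np.argmax(cov))], scan[int(np.argmin(cov))]]
    covs = [_disk_coverage(pattern, tumor_diameter, ph) for ph in phase_offsets]
    return float(np.mean(covs)), float(min(covs)), float(max(covs))


def widths_from_profile(
    x,
    dose,
    level: float = 0.5,
    kind: str = "planar_array",
    field_extent: float = 20.0,
) -> Tuple[float, float]:
    """Read peak and valley widths back from a sampled lateral profile.

    The peak width is the mean full width at ``valley + level*(peak-valley)``
    over all complete peaks in the profile; the valley width is the
    peak-to-peak period minus the peak width.  For a uniform field both
    widths equal the field extent by convention.
    """
    x = np.asarray(x, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if kind == "uniform":
        return field_extent, field_extent
    peak, valley = float(dose.max()), float(dose.min())
    if peak <= valley:
        raise ValueError("flat profile: widths undefined for an array")
    thr = valley + level * (peak - valley)
    above = dose >= thr
    # rising/falling edges with linear interpolation of the crossing point
    idx = np.flatnonzero(np.diff(above.astype(int)) != 0)
    crossings = []
    for i in idx:
        x0, x1 = x[i], x[i + 1]
        d0, d1 = dose[i], dose[i + 1]
        crossings.append(x0 + (thr - d0) / (d1 - d0) * (x1 - x0))
    if kind == "half_field":
        if len(crossings) < 1:
            raise ValueError("no threshold crossing found")
        # single edge splits the field into irradiated / shielded halves
        w_peak = field_extent / 2.0
        return w_peak, field_extent - w_peak
    rising = [c for i, c in zip(idx, crossings) if not above[i]]
    falling = [c for i, c in zip(idx, crossings) if above[i]]
    widths = []
    for rise in rising:
        nxt = [f for f in falling if f > rise]
        if nxt:
            widths.append(nxt[0] - rise)
    if not widths:
        raise ValueError("profile contains no complete peak")
    w_peak = float(np.mean(widths))
    if len(rising) >= 2:
        period = float(np.mean(np.diff(sorted(rising))))
    else:
        raise ValueError("profile must contain at least one full period")
    return w_peak, period - w_peak


def sphere_mask(grid: DoseGrid, center: Tuple[float, float, float], diameter: float) -> np.ndarray:
    """Boolean lattice mask of a sphere, clipped to the grid."""
    r = diameter / 2.0
    X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
    m = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= r**2
    if not m.any():
        raise ValueError("region does not intersect the grid")
    return m


def _region_eud_2d(
    pattern: BeamPattern,
    depth: DepthDoseModel,
    a: float,
    diameter: float,
    center_depth: float,
    dx: float = 0.01,
    dz: float = 0.05,
    zmax: float = 10.0,
) -> float:
    """EUD over a sphere using the separability of the field.

    Doses do not vary along y, so each (x, z) column carries a weight equal
    to the chord length of the sphere along y; this reduces the volumetric
    power mean to a weighted 2D one at fine lateral resolution.
    """
    r = diameter / 2.0
    x = np.arange(-r + dx / 2.0, r, dx)
    zlo, zhi = max(0.0, center_depth - r), min(zmax, center_depth + r)
    z = np.arange(zlo + dz / 2.0, zhi, dz)
    if z.size == 0 or x.size == 0:
        raise ValueError("region does not intersect the modelled depth range")
    X, Z = np.meshgrid(x, z, indexing="ij")
    chord2 = r**2 - X**2 - (Z - center_depth) ** 2
    w = 2.0 * np.sqrt(np.maximum(chord2, 0.0))
    d = lateral_profile(pattern, x)[:, None] * depth_curve(depth, z)[None, :]
    sel = w > 0
    return eud(d[sel], a, weights=w[sel])


def summarize_arm(
    name: str,
    params: EUDParams = EUDParams(),
    positional_phases: Optional[Sequence[float]] = None,
) -> ArmDosimetry:
    """All nine dosimetric parameters for a preset study arm.

    For the 2 mm arm the percentage volume irradiated and the EUDs are
    positional averages over the maximum- and minimum-coverage tumour
    positions; other arrays are effectively phase-invariant at the tumour
    scale.
    """
    pattern, depth, meta = arm_preset(name)

    if pattern.peak_dose_surface == 0.0:  # untreated arm
        return ArmDosimetry(
            arm=name, vol_avg_dose=0.0, peak_dose=0.0, valley_dose=0.0,
            tumor_eud=0.0, normal_eud=0.0, pvdr=None,
            peak_width=0.0, valley_width=0.0,
            pct_volume_irradiated=0.0, pct_volume_min=0.0, pct_volume_max=0.0,
        )

    pct, pct_min, pct_max = percent_volume_irradiated(
        pattern, params.tumor_diameter, phase_offsets=positional_phases
    )

    # volume-average dose over the field within the tumour depth
    nx = 4000
    xs = np.linspace(-pattern.field_extent / 2.0, pattern.field_extent / 2.0, nx)
    zs = np.arange(0.05, 10.0, 0.1)
    dose_xz = lateral_profile(pattern, xs)[:, None] * depth_curve(depth, zs)[None, :]
    vol_avg = float(dose_xz.mean())

    # EUDs, positionally averaged for the 2 mm arm
    if pattern.kind == "planar_array" and name == "20Gy2mmSFRT":
        if positional_phases is None:
            scan = np.linspace(0.0, pattern.period, 101)
            cov = [_disk_coverage(pattern, params.tumor_diameter, ph) for ph in scan]
            positional_phases = [scan[int(np.argmax(cov))], scan[int(np.argmin(cov))]]
        phases = list(positional_phases)
    else:
        phases = [0.0]
    from dataclasses import replace as _replace

    t_euds, n_euds = [], []
    for ph in phases:
        pat = _replace(pattern, phase=pattern.phase + ph)
        t_euds.append(
            _region_eud_2d(pat, depth, params.a_tumor,
                           params.tumor_diameter, params.tumor_center_depth)
        )
        n_euds.append(
            _region_eud_2d(pat, depth, params.a_normal,
                           params.normal_diameter, params.tumor_center_depth)
        )

    return ArmDosimetry(
        arm=name,
        vol_avg_dose=vol_avg,
        peak_dose=pattern.peak_dose_surface,
        valley_dose=pattern.valley_dose_surface,
        tumor_eud=float(np.mean(t_euds)),
        normal_eud=float(np.mean(n_euds)),
        pvdr=pvdr(pattern.peak_dose_surface, pattern.valley_dose_surface),
        peak_width=pattern.peak_width,
        valley_width=pattern.valley_width,
        pct_volume_irradiated=pct,
        pct_volume_min=pct_min,
        pct_volume_max=pct_max,
    )
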