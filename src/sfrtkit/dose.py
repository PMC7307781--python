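"""Parametric kV SFRT dose distributions.

A spatially fractionated field is modelled as the product of a lateral
peak/valley profile and an exponential depth-dose curve (separable in x and
z, constant along y — the direction parallel to the beam planes).  Lateral
profiles are trapezoidal: rectangular plateaus anchored to the measured
surface peak/valley doses, joined by linear penumbra ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BeamPattern",
    "DepthDoseModel",
    "DoseGrid",
    "lateral_profile",
    "depth_curve",
    "compose_grid",
    "calibrate_mu",
    "arm_preset",
    "ARM_NAMES",
]

#: lateral span of every collimated field in the six-arm design (mm)
FIELD_EXTENT_MM = 20.0

#: default lattice spacing (dx, dy, dz) in mm; dx resolves the 0.31 mm
#: minibeam apertures with ~31 samples
DEFAULT_RESOLUTION = (0.01, 1.0, 0.1)

#: default lattice extent (x, y, z) in mm; z spans the 1 cm tumour depth
DEFAULT_EXTENT = (20.0, 20.0, 10.0)


@dataclass(frozen=True)
class BeamPattern:
    """Lateral beam structure of one treatment arm at the phantom surface.

    Parameters
    ----------
    kind:
        ``"uniform"`` (open field), ``"half_field"`` (one half of the field
        irradiated) or ``"planar_array"`` (periodic planar beam array).
    peak_dose_surface, valley_dose_surface:
        plateau doses in Gy at the surface.
    peak_width, valley_width:
        aperture width and gap between adjacent aperture edges, mm.
    penumbra_width:
        width of the linear ramp joining a peak plateau to the neighbouring
        valley plateau, mm (model parameter, not a measured quantity).
    field_extent:
        lateral span of the collimated field, mm.
    phase:
        lateral offset of the central peak centre from x = 0, mm.  Used by
        the positional-averaging analysis of the 2 mm arm.
    """

    kind: str
    peak_dose_surface: float
    valley_dose_surface: float
    peak_width: float
    valley_width: float
    penumbra_width: float = 0.0
    field_extent: float = FIELD_EXTENT_MM
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "half_field", "planar_array"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not (self.peak_dose_surface >= self.valley_dose_surface >= 0.0):
            raise ValueError("require peak_dose_surface >= valley_dose_surface >= 0")
        if self.peak_width <= 0 and self.kind != "uniform":
            raise ValueError("peak_width must be > 0")
        if self.valley_width < 0 or self.penumbra_width < 0:
            raise ValueError("widths must be non-negative")
        if self.kind == "uniform":
            if self.peak_dose_surface != self.valley_dose_surface:
                raise ValueError("uniform field requires peak == valley dose")

    @property
    def period(self) -> float:
        return self.peak_width + self.valley_width


@dataclass(frozen=True)
class DepthDoseModel:
    """Single effective-attenuation exponential depth dose, exp(-mu*z).

    ``mu`` is an effective linear attenuation coefficient (1/mm) lumping
    attenuation and scatter buildup of the 320 kV beam into one monotone
    curve normalised to 1 at the surface.
    """

    mu: float
    max_depth: float = 10.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be > 0")


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed dose (Gy) on a regular 3D lattice.

    Axes: x lateral across the peaks, y along the peak planes, z depth from
    the irradiated surface.  The origin sits at the field centre on the
    surface; voxel k along an axis covers the half-open bin
    ``[x0 + k*d, x0 + (k+1)*d)``.  Lateral axes are sampled at bin centres;
    depth is sampled at each bin's upper surface so the irradiated surface
    (z = 0, where the peak dose is attained) lies on the grid.
    """

    values: np.ndarray  # shape (nx, ny, nz)
    voxel_size: Tuple[float, float, float]
    origin: Tuple[float, float, float]  # lower bin edge of voxel (0, 0, 0)

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        d = self.voxel_size[axis]
        return self.origin[axis] + d * (np.arange(n) + 0.5)

    @property
    def x(self) -> np.ndarray:
        return self.axis_centers(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis_centers(1)

    @property
    def z(self) -> np.ndarray:
        d = self.voxel_size[2]
        return self.origin[2] + d * np.arange(self.values.shape[2])


def lateral_profile(pattern: BeamPattern, x) -> np.ndarray:
    """Surface dose (Gy) at lateral positions ``x`` (mm).

    Planar arrays are periodic with period ``peak_width + valley_width`` and
    a peak centred at ``x = phase``; outside the collimated field the array
    profile falls to the valley (scatter floor) while uniform and half
    fields fall to zero.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("positions must be finite")
    half = pattern.field_extent / 2.0
    pen = pattern.penumbra_width

    if pattern.kind == "uniform":
        # open field: plateau inside, linear ramp to 0 across the field edge
        d_out = np.maximum(np.abs(x) - half, 0.0)
        if pen > 0:
            ramp = np.clip(1.0 - d_out / pen, 0.0, 1.0)
        else:
            ramp = (d_out == 0).astype(float)
        return pattern.peak_dose_surface * ramp

    if pattern.kind == "half_field":
        # irradiated half [-half, 0], shielded half (0, half]; ramp at x=0
        if pen > 0:
            t = np.clip((pen / 2.0 - x) / pen, 0.0, 1.0)
        else:
            t = (x <= 0).astype(float)
        dose = pattern.valley_dose_surface + t * (
            pattern.peak_dose_surface - pattern.valley_dose_surface
        )
        dose = np.where(np.abs(x) > half, 0.0, dose)
        return dose

    # planar array
    p = pattern.period
    xm = np.mod(x - pattern.phase + p / 2.0, p) - p / 2.0  # distance-to-peak-centre frame
    d = np.abs(xm)
    hw = pattern.peak_width / 2.0
    peak, valley = pattern.peak_dose_surface, pattern.valley_dose_surface
    if pen > 0:
        t = np.clip(1.0 - (d - hw) / pen, 0.0, 1.0)  # 1 on plateau, 0 in valley
    else:
        t = (d <= hw).astype(float)
    dose = valley + t * (peak - valley)
    return np.where(np.abs(x) > half, valley, dose)


def depth_curve(model: DepthDoseModel, z) -> np.ndarray:
    """Relative depth dose exp(-mu*z); 1 at the surface."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be >= 0")
    return np.exp(-model.mu * z)


def calibrate_mu(
    surface_dose: float = 20.8,
    volume_average: float = 20.0,
    depth: float = 10.0,
) -> float:
    """Effective attenuation coefficient reconciling the open-field surface
    dose with its volume-average over the tumour depth.

    Solves ``(1 - exp(-mu*depth)) / (mu*depth) = volume_average/surface_dose``
    by bisection.  With the study's printed pair (20.8 Gy surface, 20 Gy
    average over 1 cm) this gives mu ~ 0.0079 /mm.
    """
    ratio = volume_average / surface_dose
    if not 0 < ratio < 1:
        raise ValueError("volume average must lie strictly below the surface dose")
    f = lambda mu: (1.0 - np.exp(-mu * depth)) / (mu * depth) - ratio
    return brentq(f, 1e-9, 10.0, xtol=1e-12)


def compose_grid(
    pattern: BeamPattern,
    depth: DepthDoseModel,
    extent: Tuple[float, float, float] = DEFAULT_EXTENT,
    resolution: Tuple[float, float, float] = DEFAULT_RESOLUTION,
) -> DoseGrid:
    """Separable 3D dose grid: values(x, y, z) = lateral(x) * depth(z)."""
    ex, ey, ez = extent
    dx, dy, dz = resolution
    if min(ex, ey, ez) <= 0:
        raise ValueError("zero-sized extent")
    if pattern.kind == "planar_array" and dx > pattern.peak_width / 5.0:
        raise ValueError(
            f"dx={dx} too coarse for peak width {pattern.peak_width} "
            "(need dx <= peak_width/5)"
        )
    nx, ny, nz = (max(1, int(round(e / d))) for e, d in zip(extent, resolution))
    origin = (-ex / 2.0, -ey / 2.0, 0.0)
    xc = origin[0] + dx * (np.arange(nx) + 0.5)
    zc = dz * np.arange(nz)
    lat = lateral_profile(pattern, xc)
    pdd = depth_curve(depth, zc)
    values = lat[:, None, None] * np.ones(ny)[None, :, None] * pdd[None, None, :]
    return DoseGrid(values=values, voxel_size=(dx, dy, dz), origin=origin)


# ---------------------------------------------------------------------------
# Six-arm study presets
# ---------------------------------------------------------------------------

_MU_CALIBRATED = calibrate_mu()

#: penumbra ramp half-widths by collimator scale (mm)
_PEN_MINIBEAM = 0.05
_PEN_BROAD = 0.5

_ARM_PRESETS = {
    "Untreated": dict(
        pattern=BeamPattern("uniform", 0.0, 0.0, FIELD_EXTENT_MM, FIELD_EXTENT_MM,
                            0.0),
        prescription_gy=0.0,
        n_animals=8,
    ),
    "20GyUniformRT": dict(
        pattern=BeamPattern("uniform", 20.8, 20.8, FIELD_EXTENT_MM, FIELD_EXTENT_MM,
                            _PEN_BROAD),
        prescription_gy=20.0,
        n_animals=8,
    ),
    "20GyHalfSFRT": dict(
        pattern=BeamPattern("half_field", 39.0, 3.1, 10.0, 10.0, _PEN_BROAD),
        prescription_gy=20.0,
        n_animals=5,
    ),
    "20Gy2mmSFRT": dict(
        pattern=BeamPattern("planar_array", 34.5, 6.2, 2.2, 2.0, _PEN_BROAD),
        prescription_gy=17.63,  # delivered volume-average; 20 Gy was intended
        n_animals=6,
    ),
    "20GySFRT": dict(
        pattern=BeamPattern("planar_array", 91.0, 6.8, 0.31, 0.9, _PEN_MINIBEAM),
        prescription_gy=20.0,
        n_animals=9,
    ),
    "50GySFRT": dict(
        # same collimator geometry as 20GySFRT, 2.5x output
        pattern=BeamPattern("planar_array", 225.0, 16.8, 0.31, 0.9, _PEN_MINIBEAM),
        prescription_gy=50.0,
        n_animals=6,
    ),
}

ARM_NAMES = tuple(_ARM_PRESETS)


def arm_preset(name: str, phase: float = 0.0):
    """Return ``(BeamPattern, DepthDoseModel, metadata)`` for a study arm.

    ``phase`` shifts the array laterally (used by the 2 mm arm positional
    averaging); it is ignored for uniform/half fields.
    """
    try:
        spec = _ARM_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown arm {name!r}; expected one of {', '.join(ARM_NAMES)}"
        ) from None
    pattern = spec["pattern"]
    if phase != 0.0 and pattern.kind == "planar_array":
        pattern = replace(pattern, phase=phase)
    meta = {
        "arm": name,
        "prescription_gy": spec["prescription_gy"],
        "n_animals": spec["n_animals"],
    }
    return pattern, DepthDoseModel(mu=_MU_CALIBRATED), meta
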