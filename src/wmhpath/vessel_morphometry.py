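"""Sclerotic-index morphometry of white-matter arteries and arterioles.

The sclerotic index SI = 1 - Dint/Dext measures relative vessel-wall
thickness on a transverse section: Dint is the luminal (internal) diameter
and Dext the outer (external) diameter.  Normal vessels sit around
SI 0.2-0.3; 0.3-0.5 indicates mild-to-moderate small vessel disease and
SI > 0.5 severe disease.

``measure_vessel`` emulates interactive caliper measurement on a single
H&E-stained vessel cross-section: diameters are taken along three
orientations 60 degrees apart through the wall centroid and the three
per-orientation SI values are averaged.  Only vessels with external
diameter above 50 um are eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VesselMeasurement",
    "NoAnnulusError",
    "IneligibleVesselError",
    "sclerotic_index",
    "measure_vessel",
    "aggregate_si",
    "svd_band",
    "MIN_EXTERNAL_DIAMETER_UM",
    "VESSELS_PER_BLOCK",
]

MIN_EXTERNAL_DIAMETER_UM = 50.0
VESSELS_PER_BLOCK = 8

#: Luminance above which a pixel is treated as background/lumen rather than
#: stained wall (8-bit scale; eosinophilic walls render far darker).
_WALL_LUMINANCE_CUTOFF = 215.0


class NoAnnulusError(ValueError):
    """No annular vessel wall could be found in the field."""


class IneligibleVesselError(ValueError):
    """Vessel fails the >50 um external-diameter eligibility rule."""


@dataclass(frozen=True)
class VesselMeasurement:
    """Three paired diameter measurements and the resulting sclerotic index."""

    d_int: tuple[float, float, float]  # um, one per orientation
    d_ext: tuple[float, float, float]  # um
    si: float

    def __post_init__(self) -> None:
        for di, de in zip(self.d_int, self.d_ext):
            if not (0 < di < de):
                raise ValueError("each internal diameter must be positive and below the external")
        if not (0 < self.si < 1):
            raise ValueError("si must lie in (0, 1)")

    @property
    def mean_d_ext(self) -> float:
        return float(np.mean(self.d_ext))


def sclerotic_index(d_int: float, d_ext: float) -> float:
    """SI = 1 - (internal diameter / external diameter)."""
    if d_int <= 0 or d_ext <= 0:
        raise ValueError("diameters must be positive")
    if d_int >= d_ext:
        raise ValueError(f"internal diameter ({d_int}) must be below external ({d_ext})")
    return 1.0 - d_int / d_ext


def _profile_diameters(
    wall: np.ndarray, centroid: tuple[float, float], theta: float, step: float = 0.25
) -> tuple[float, float]:
    """Caliper diameters (px) of lumen and wall along one orientation.

    Samples the wall mask on a line through the centroid at angle ``theta``
    (radians), locating the outer wall edges (external diameter) and the two
    inner wall edges flanking the lumen (internal diameter) at the half-level
    crossings of a bilinear profile.
    """
    h, w = wall.shape
    half = float(np.hypot(h, w)) / 2.0 + 2.0
    t = np.arange(-half, half + step, step)
    rows = centroid[0] + t * np.sin(theta)
    cols = centroid[1] + t * np.cos(theta)
    prof = ndimage.map_coordinates(wall.astype(float), [rows, cols], order=1, cval=0.0)
    on = prof >= 0.5
    idx = np.flatnonzero(on)
    if idx.size == 0:
        raise NoAnnulusError("no wall pixels along measurement line")
    first, last = idx[0], idx[-1]
    d_ext = (t[last] - t[first])
    # lumen: the largest interior gap between wall runs
    interior = on[first : last + 1]
    off = np.flatnonzero(~interior)
    if off.size == 0:
        raise NoAnnulusError("no lumen detected: wall profile has no interior gap")
    # split 'off' into runs, take the longest
    splits = np.split(off, np.flatnonzero(np.diff(off) > 1) + 1)
    gap = max(splits, key=len)
    # inner edges sit half a step outside the open run
    d_int = (gap[-1] - gap[0] + 1) * step
    return d_int, d_ext


def measure_vessel(
    raster: np.ndarray,
    pixel_size: float,
    orientations_deg: Sequence[float] = (0.0, 60.0, 120.0),
) -> VesselMeasurement:
    """Measure one annular vessel in an RGB field; returns the SI.

    The wall is segmented by luminance, diameters are read along three
    orientations through the wall centroid, and the per-vessel SI is the mean
    of the three per-orientation SI values.  Vessels with mean external
    diameter <= 50 um are rejected as ineligible.
    """
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError("raster must be an (H, W, 3) RGB array")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    lum = raster.astype(float).mean(axis=2)
    wall = lum < _WALL_LUMINANCE_CUTOFF
    if not wall.any():
        raise NoAnnulusError("no stained wall detected in field")
    rr, cc = np.nonzero(wall)
    centroid = (float(rr.mean()), float(cc.mean()))
    d_ints: list[float] = []
    d_exts: list[float] = []
    sis: list[float] = []
    for deg in orientations_deg:
        di_px, de_px = _profile_diameters(wall, centroid, np.deg2rad(deg))
        di, de = di_px * pixel_size, de_px * pixel_size
        d_ints.append(di)
        d_exts.append(de)
        sis.append(sclerotic_index(di, de))
    if float(np.mean(d_exts)) <= MIN_EXTERNAL_DIAMETER_UM:
        raise IneligibleVesselError(
            f"external diameter {np.mean(d_exts):.1f} um <= {MIN_EXTERNAL_DIAMETER_UM} um"
        )
    return VesselMeasurement(tuple(d_ints), tuple(d_exts), float(np.mean(sis)))


def aggregate_si(per_region: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Regional mean SIs and the hemisphere total.

    ``per_region`` maps region -> vessel SI values.  The frontal region pools
    the pre- and mid-frontal blocks and therefore carries 16 values; the
    temporal, parietal and occipital regions carry 8 each (one block of eight
    randomly selected vessels).  Total = mean of the four regional means.
    """
    expected = {"frontal": 2 * VESSELS_PER_BLOCK, "temporal": VESSELS_PER_BLOCK,
                "parietal": VESSELS_PER_BLOCK, "occipital": VESSELS_PER_BLOCK}
    missing = [r for r in expected if r not in per_region]
    if missing:
        raise ValueError(f"missing regions: {', '.join(missing)}")
    out: dict[str, float] = {}
    for region, n_expected in expected.items():
        vals = np.asarray(per_region[region], dtype=float)
        if vals.size != n_expected:
            raise ValueError(
                f"{region} expects {n_expected} vessel SIs, got {vals.size}"
            )
        out[region] = float(vals.mean())
    out["total"] = float(np.mean([out[r] for r in expected]))
    return out


def svd_band(si: float) -> str:
    """Severity band of a sclerotic index.

    <= 0.3 is within the normal range, (0.3, 0.5] indicates mild-to-moderate
    small vessel disease, and > 0.5 severe disease.  The band edges are
    assigned half-open because the published ranges overlap at 0.3 and 0.5.
    """
    if not (0 < si < 1):
        raise ValueError("si must lie in (0, 1)")
    if si <= 0.3:
        return "normal"
    if si <= 0.5:
        return "mild_moderate"
    return "severe"
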