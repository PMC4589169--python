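"""Ground-truthed synthetic inputs for the measurement chain.

Four generators, each an exact dual of a downstream measurement:

* IHC montages — DAB-brown immunopositive structures (tangles, neuropil
  threads, plaques, sub-100 um^2 APP-like specks) painted strictly inside
  the marker's RGB threshold box on a haematoxylin-like background painted
  strictly outside it, so the pixel classifier recovers the painted mask
  exactly.
* Vessel cross-sections — concentric similar ellipses (wall annulus) of
  known internal/external diameter, so the caliper measurement can be
  checked against SI = 1 - Dint/Dext in closed form.
* Lesion masks — discs of requested caliper diameters, optionally joined
  by thin connecting bridges, on a field with a mm scale.
* Cohorts — a Gaussian copula over (age, tau burden, amyloid burden,
  sclerotic index, WMH severity) latents with configurable correlation,
  AD-vs-control mean shifts, monotone mapping to observable scales, and
  probit-style discretization of the WMH latent to the 0-3 ARWMC ordinal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage import draw, morphology

from .ihc_quant import (
    DEFAULT_THRESHOLDS,
    MontageImage,
    RGBThresholdSpec,
    classify_pixels,
)
from . import wmh_rating

__all__ = [
    "IHCSceneSpec",
    "IHCMontageTruth",
    "make_ihc_montage",
    "VesselSceneSpec",
    "make_vessel_image",
    "LesionSceneSpec",
    "make_lesion_mask",
    "CohortConfig",
    "make_cohort",
    "LATENT_VARS",
    "default_latent_corr",
    "latent_corr_with_partial",
    "DEFAULT_TILE_PX",
    "DEFAULT_PIXEL_SIZE_UM",
    "MONTAGE_GRID",
    "montage_area_mm2",
]

# --------------------------------------------------------------------------
# acquisition geometry

#: 3x3 tiles of 512 px at 0.85 um/px -> field side 1305.6 um, area 1.7046 mm^2
DEFAULT_TILE_PX = 512
DEFAULT_PIXEL_SIZE_UM = 0.85
MONTAGE_GRID = 3

#: physical field side in um, held fixed across alternate tile geometries
FIELD_SIDE_UM = MONTAGE_GRID * DEFAULT_TILE_PX * DEFAULT_PIXEL_SIZE_UM


def montage_area_mm2(tile_px: int = DEFAULT_TILE_PX,
                     pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                     grid: int = MONTAGE_GRID) -> float:
    """Physical area (mm^2) of a grid x grid montage of square tiles."""
    side_um = grid * tile_px * pixel_size
    return (side_um / 1000.0) ** 2


def pixel_size_for_field(tile_px: int, grid: int = MONTAGE_GRID) -> float:
    """Pixel size (um/px) that keeps the montage at the standard field area."""
    return FIELD_SIDE_UM / (grid * tile_px)


# --------------------------------------------------------------------------
# IHC montages

STRUCTURE_KINDS = ("tangle", "thread", "plaque", "app_speck")

#: painted non-speck structures are kept safely above the 100 um^2 size
#: filter; APP-like specks safely below it
_MIN_STRUCT_AREA_UM2 = 110.0
_MAX_SPECK_AREA_UM2 = 90.0
_MAX_PACKING_FRACTION = 0.25


@dataclass(frozen=True)
class IHCSceneSpec:
    """Parameters of one synthetic IHC montage."""

    tile_px: int = DEFAULT_TILE_PX
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    n_structures: int = 20
    structure_kinds: tuple[str, ...] = ("tangle", "thread", "plaque")
    target_fraction: Optional[float] = None
    marker: str = "AT8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.target_fraction is not None and not (0 <= self.target_fraction <= 1):
            raise ValueError("target_fraction must lie in [0, 1]")
        unknown = set(self.structure_kinds) - set(STRUCTURE_KINDS)
        if unknown:
            raise ValueError(f"unknown structure kinds: {sorted(unknown)}")
        if self.marker not in DEFAULT_THRESHOLDS:
            raise ValueError(f"marker must be one of {sorted(DEFAULT_THRESHOLDS)}")


@dataclass
class IHCMontageTruth:
    """A generated montage with its exact ground truth."""

    image: MontageImage
    mask: np.ndarray               # all painted immunopositive pixels
    speck_mask: np.ndarray         # the sub-100 um^2 APP-like subset
    true_fraction: float           # painted positive fraction (all structures)
    true_fraction_filtered: float  # after excluding the speck subset
    spec: IHCSceneSpec


def _interior_colors(rng: np.random.Generator, spec: RGBThresholdSpec, n: int) -> np.ndarray:
    """``n`` colors sampled uniformly, strictly inside the marker's RGB box."""
    return np.column_stack([
        rng.integers(lo + 1, hi, size=n)  # [lo+1, hi-1]
        for lo, hi in (spec.r_range, spec.g_range, spec.b_range)
    ]).astype(np.uint8)


def _background(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Haematoxylin-like background, guaranteed outside both marker boxes.

    The red channel is kept >= 185, above the red upper bound of both marker
    boxes (170 and 180), so no background pixel can classify positive.
    """
    h, w = shape
    r = rng.integers(185, 236, size=(h, w), dtype=np.int16)
    g = np.clip(r - rng.integers(5, 30, size=(h, w)), 0, 255)
    b = np.clip(r + rng.integers(5, 21, size=(h, w)), 0, 255)
    return np.stack([r, g, b], axis=-1).astype(np.uint8)


def _rasterize_structure(
    rng: np.random.Generator, kind: str, canvas: int, px_area_um2: float
) -> Optional[np.ndarray]:
    """Boolean mask of one candidate structure on a blank canvas."""
    out = np.zeros((canvas, canvas), dtype=bool)
    min_px = int(math.ceil(_MIN_STRUCT_AREA_UM2 / px_area_um2))
    if kind == "app_speck":
        max_px = int(math.floor(_MAX_SPECK_AREA_UM2 / px_area_um2))
        if max_px < 1:
            return None
        n_px = int(rng.integers(1, max_px + 1))
        radius = max(1.0, math.sqrt(n_px / math.pi))
        r0 = rng.integers(5, canvas - 5)
        c0 = rng.integers(5, canvas - 5)
        rr, cc = draw.disk((r0, c0), radius, shape=out.shape)
        out[rr, cc] = True
        # trim to stay strictly under the speck ceiling
        while out.sum() * px_area_um2 > _MAX_SPECK_AREA_UM2:
            rr, cc = np.nonzero(out)
            out[rr[-1], cc[-1]] = False
        if not out.any():
            return None
        return out
    if kind == "plaque":
        area_um2 = rng.uniform(200.0, 1200.0)
        radius = math.sqrt(area_um2 / math.pi) / math.sqrt(px_area_um2)
        r0 = rng.integers(int(radius) + 2, canvas - int(radius) - 2)
        c0 = rng.integers(int(radius) + 2, canvas - int(radius) - 2)
        rr, cc = draw.disk((r0, c0), radius, shape=out.shape)
        out[rr, cc] = True
    elif kind == "tangle":
        area_um2 = rng.uniform(150.0, 500.0)
        ab = area_um2 / math.pi / px_area_um2  # product of semi-axes in px^2
        ratio = rng.uniform(1.5, 3.0)          # flame-like elongation
        a = math.sqrt(ab * ratio)
        b = math.sqrt(ab / ratio)
        pad = int(a) + 2
        r0 = rng.integers(pad, canvas - pad)
        c0 = rng.integers(pad, canvas - pad)
        rr, cc = draw.ellipse(r0, c0, a, b, shape=out.shape,
                              rotation=rng.uniform(0, math.pi))
        out[rr, cc] = True
    elif kind == "thread":
        length_um = rng.uniform(60.0, 200.0)
        length_px = max(4, int(length_um / math.sqrt(px_area_um2)))
        pad = length_px // 2 + 3
        if pad * 2 + 4 >= canvas:
            length_px = canvas // 3
            pad = length_px // 2 + 3
        r0 = int(rng.integers(pad, canvas - pad))
        c0 = int(rng.integers(pad, canvas - pad))
        theta = rng.uniform(0, math.pi)
        r1 = int(round(r0 + length_px * math.sin(theta) / 2))
        c1 = int(round(c0 + length_px * math.cos(theta) / 2))
        r2 = int(round(r0 - length_px * math.sin(theta) / 2))
        c2 = int(round(c0 - length_px * math.cos(theta) / 2))
        rr, cc = draw.line(r1, c1, r2, c2)
        keep = (rr >= 0) & (rr < canvas) & (cc >= 0) & (cc < canvas)
        out[rr[keep], cc[keep]] = True
        out = morphology.dilation(out, morphology.disk(1))
    else:
        raise ValueError(f"unknown structure kind: {kind}")
    if out.sum() * px_area_um2 < _MIN_STRUCT_AREA_UM2:
        # too small to survive the size filter: thicken once, else reject
        out = morphology.dilation(out, morphology.disk(1))
        if out.sum() * px_area_um2 < _MIN_STRUCT_AREA_UM2:
            return None
    return out


def make_ihc_montage(spec: IHCSceneSpec) -> IHCMontageTruth:
    """Render a 3x3-tile montage with exact ground truth.

    Every painted immunopositive pixel lies strictly inside the marker's RGB
    box and every background pixel strictly outside it (verified before
    returning).  Structures never touch (8-connectivity), non-speck
    structures exceed the 100 um^2 size filter and APP-like specks stay
    below it.  ``true_fraction`` is the exact painted positive-pixel
    fraction.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = MONTAGE_GRID * spec.tile_px
    threshold = DEFAULT_THRESHOLDS[spec.marker]
    rgb = _background(rng, (canvas, canvas))
    mask = np.zeros((canvas, canvas), dtype=bool)
    speck_mask = np.zeros_like(mask)
    px_area = spec.pixel_size**2
    total_px = canvas * canvas

    if spec.target_fraction is not None and spec.target_fraction > _MAX_PACKING_FRACTION:
        raise ValueError(
            f"target_fraction {spec.target_fraction} exceeds the packing limit "
            f"{_MAX_PACKING_FRACTION} at this geometry"
        )

    def paint(rr: np.ndarray, cc: np.ndarray, kind: str) -> None:
        rgb[rr, cc] = _interior_colors(rng, threshold, len(rr))
        mask[rr, cc] = True
        if kind == "app_speck":
            speck_mask[rr, cc] = True

    blank = spec.target_fraction == 0
    if not blank:
        kinds = list(spec.structure_kinds) or ["plaque"]
        placed = 0
        attempts = 0
        max_attempts = 200 * max(spec.n_structures, 1) + 2000
        want_more = True
        while want_more:
            if attempts > max_attempts:
                if spec.target_fraction is not None and mask.sum() / total_px < spec.target_fraction:
                    raise ValueError(
                        f"cannot reach target_fraction {spec.target_fraction} at "
                        f"tile_px={spec.tile_px}: packing limit hit after "
                        f"{attempts} placement attempts"
                    )
                break
            attempts += 1
            kind = kinds[placed % len(kinds)]
            struct = _rasterize_structure(rng, kind, canvas, px_area)
            if struct is None:
                continue
            rr, cc = np.nonzero(struct)
            # keep structures 8-disconnected from each other: dilate within
            # the structure's bounding box only (placement stays cheap)
            r0, r1 = max(rr.min() - 2, 0), min(rr.max() + 3, canvas)
            c0, c1 = max(cc.min() - 2, 0), min(cc.max() + 3, canvas)
            grown = morphology.dilation(
                struct[r0:r1, c0:c1], morphology.disk(1)
            )
            if (grown & mask[r0:r1, c0:c1]).any():
                continue
            paint(rr, cc, kind)
            placed += 1
            if spec.target_fraction is None:
                want_more = placed < spec.n_structures
            else:
                want_more = (placed < spec.n_structures
                             or mask.sum() / total_px < spec.target_fraction)

    image = MontageImage(rgb=rgb, pixel_size=spec.pixel_size)
    # generator/classifier duality check: painted and classified masks agree
    classified = classify_pixels(image, threshold)
    if not np.array_equal(classified, mask):
        raise AssertionError("generator invariant violated: painted mask != classified mask")
    true_fraction = float(mask.sum()) / total_px
    true_filtered = float((mask & ~speck_mask).sum()) / total_px
    return IHCMontageTruth(image, mask, speck_mask, true_fraction, true_filtered, spec)


# --------------------------------------------------------------------------
# vessel cross-sections

_VESSEL_BG = np.array([246, 242, 247], dtype=np.int16)
_VESSEL_WALL = np.array([193, 106, 134], dtype=np.int16)


@dataclass(frozen=True)
class VesselSceneSpec:
    """One annular vessel cross-section of known geometry."""

    d_int: float                  # um, luminal diameter (major axis)
    d_ext: float                  # um, external diameter (major axis)
    eccentricity: float = 0.0     # shared by wall and lumen ellipses
    rotation: float = 0.0         # degrees
    pixel_size: float = 1.0       # um/px
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.d_int < self.d_ext):
            raise ValueError("require 0 < d_int < d_ext")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must lie in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def true_si(self) -> float:
        return 1.0 - self.d_int / self.d_ext


def make_vessel_image(spec: VesselSceneSpec) -> tuple[np.ndarray, float]:
    """Render the vessel annulus; returns (RGB raster, true SI).

    The wall and lumen are concentric similar ellipses (same eccentricity and
    orientation), so the internal/external diameter ratio — and hence the SI —
    is identical along every orientation through the centre.
    """
    rng = np.random.default_rng(spec.seed)
    side = int(math.ceil(spec.d_ext / spec.pixel_size * 1.5)) | 1
    c = side / 2.0 - 0.5
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    yy -= c
    xx -= c
    th = math.radians(spec.rotation)
    u = xx * math.cos(th) + yy * math.sin(th)
    v = -xx * math.sin(th) + yy * math.cos(th)
    bscale = math.sqrt(1.0 - spec.eccentricity**2)

    def inside(d_um: float) -> np.ndarray:
        a = d_um / 2.0 / spec.pixel_size
        b = a * bscale
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    wall = inside(spec.d_ext) & ~inside(spec.d_int)
    rgb = np.empty((side, side, 3), dtype=np.int16)
    rgb[...] = _VESSEL_BG + rng.integers(-4, 5, size=(side, side, 3))
    rgb[wall] = _VESSEL_WALL + rng.integers(-6, 7, size=(int(wall.sum()), 3))
    return np.clip(rgb, 0, 255).astype(np.uint8), spec.true_si


# --------------------------------------------------------------------------
# lesion masks

@dataclass(frozen=True)
class LesionSceneSpec:
    """A white-matter lesion field of known component geometry."""

    field_mm: float = 100.0
    lesion_diameters: tuple[float, ...] = ()
    bridges: tuple[tuple[int, int], ...] = ()
    centers_mm: Optional[tuple[tuple[float, float], ...]] = None
    px_per_mm: float = 8.0
    bridge_width_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_mm <= 0 or self.px_per_mm <= 0:
            raise ValueError("field_mm and px_per_mm must be positive")
        if any(d <= 0 for d in self.lesion_diameters):
            raise ValueError("all lesion diameters must be positive")
        n = len(self.lesion_diameters)
        for i, j in self.bridges:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid bridge indices ({i}, {j})")
        if not (0 < self.bridge_width_mm < wmh_rating.BRIDGE_WIDTH_MM):
            raise ValueError("bridge width must be thin (< 3 mm)")
        if self.centers_mm is not None and len(self.centers_mm) != n:
            raise ValueError("centers_mm must match lesion_diameters")


class LesionOverlapError(ValueError):
    """Two lesions overlap or touch without a bridge being requested."""


def make_lesion_mask(spec: LesionSceneSpec) -> tuple[np.ndarray, float]:
    """Rasterize the lesion field; returns (binary mask, mm per pixel).

    Discs of the requested caliper diameters are placed without touching;
    bridged pairs are joined by a thin (< 3 mm wide) connecting line so they
    form a single component.  Raises if lesions cannot be placed apart, or if
    explicit centres overlap without a requested bridge.
    """
    rng = np.random.default_rng(spec.seed)
    ppm = spec.px_per_mm
    side = int(round(spec.field_mm * ppm))
    mask = np.zeros((side, side), dtype=bool)
    diams = spec.lesion_diameters
    if not diams:
        return mask, 1.0 / ppm
    radii = [d / 2.0 for d in diams]
    if any(2 * r + 2.0 > spec.field_mm for r in radii):
        raise ValueError("a lesion does not fit inside the field")
    bridge_set = {frozenset(b) for b in spec.bridges}

    def conflict(centers: list[tuple[float, float]]) -> Optional[tuple[int, int]]:
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                gap = math.dist(centers[i], centers[j]) - radii[i] - radii[j]
                if gap < 1.0:  # keep >= 1 mm clearance so discs never touch
                    return (i, j)
        return None

    if spec.centers_mm is not None:
        centers = [tuple(c) for c in spec.centers_mm]
        bad = conflict(centers)
        if bad is not None and frozenset(bad) not in bridge_set:
            raise LesionOverlapError(
                f"lesions {bad[0]} and {bad[1]} overlap but no bridge was requested"
            )
    else:
        for _ in range(500):
            centers = [
                (rng.uniform(r + 1.0, spec.field_mm - r - 1.0),
                 rng.uniform(r + 1.0, spec.field_mm - r - 1.0))
                for r in radii
            ]
            if conflict(centers) is None:
                break
        else:
            raise ValueError("could not place lesions without overlap in 500 tries")

    for (cy, cx), r in zip(centers, radii):
        rr, cc = draw.disk((cy * ppm, cx * ppm), r * ppm, shape=mask.shape)
        mask[rr, cc] = True
    if spec.bridges:
        line = np.zeros_like(mask)
        for i, j in spec.bridges:
            rr, cc = draw.line(
                int(round(centers[i][0] * ppm)), int(round(centers[i][1] * ppm)),
                int(round(centers[j][0] * ppm)), int(round(centers[j][1] * ppm)),
            )
            line[rr, cc] = True
        radius_px = max(1, int(round(spec.bridge_width_mm / 2.0 * ppm)) - 1)
        mask |= morphology.dilation(line, morphology.disk(radius_px))
    return mask, 1.0 / ppm


# --------------------------------------------------------------------------
# cohorts

LATENT_VARS = ("age", "hpt", "abeta", "si", "wmh")
REGIONS = ("frontal", "temporal", "parietal", "occipital")

#: within-case region loading: share of a regional latent's variance carried
#: by the case-level latent (the rest is regional noise)
_REGION_LOADING = 0.8

# control-group staging distributions (empirical counts of a 13-case control
# group: Braak 0 x2, 1 x1, 2 x3, 3 x6, 4 x1; Thal 0 x5, 1 x3, 2 x3, 3 x1, 4 x1)
_CTRL_BRAAK = [0, 0, 1, 2, 2, 2, 3, 3, 3, 3, 3, 3, 4]
_CTRL_THAL = [0, 0, 0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 4]


def default_latent_corr() -> np.ndarray:
    """Default latent correlation over (age, HPtau, Abeta, SI, WMH)."""
    c = np.eye(5)
    pairs = {
        ("age", "hpt"): 0.30, ("age", "abeta"): 0.30, ("age", "si"): 0.25,
        ("age", "wmh"): 0.35, ("hpt", "abeta"): 0.60, ("hpt", "si"): 0.15,
        ("hpt", "wmh"): 0.45, ("abeta", "si"): 0.15, ("abeta", "wmh"): 0.40,
        ("si", "wmh"): 0.25,
    }
    for (a, b), r in pairs.items():
        i, j = LATENT_VARS.index(a), LATENT_VARS.index(b)
        c[i, j] = c[j, i] = r
    return c


def latent_corr_with_partial(partial_hpt_wmh: float, r_age: float = 0.3) -> np.ndarray:
    """Latent correlation with a prescribed HPtau-WMH partial (given age).

    Both tau and WMH load on age with correlation ``r_age``; the marginal
    tau-WMH correlation is chosen so that the partial correlation controlling
    age equals ``partial_hpt_wmh`` exactly.
    """
    c = np.eye(5)
    i_age, i_hpt, i_wmh = (LATENT_VARS.index(v) for v in ("age", "hpt", "wmh"))
    c[i_age, i_hpt] = c[i_hpt, i_age] = r_age
    c[i_age, i_wmh] = c[i_wmh, i_age] = r_age
    rho = partial_hpt_wmh * (1.0 - r_age**2) + r_age**2
    c[i_hpt, i_wmh] = c[i_wmh, i_hpt] = rho
    return c


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic post-mortem cohort."""

    n_cases: int = 36
    prop_ad: float = 23.0 / 36.0
    latent_corr: Optional[np.ndarray] = None   # defaults to default_latent_corr()
    group_shift: tuple[float, ...] = (0.0, 1.8, 1.8, 0.0, 0.6)
    arwmc_cutpoints: tuple[float, float, float] = (-0.2, 0.8, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not (0 <= self.prop_ad <= 1):
            raise ValueError("prop_ad must lie in [0, 1]")
        if len(self.group_shift) != len(LATENT_VARS):
            raise ValueError(f"group_shift needs {len(LATENT_VARS)} entries")
        cp = self.arwmc_cutpoints
        if not (cp[0] < cp[1] < cp[2]):
            raise ValueError("arwmc_cutpoints must be strictly increasing")

    def corr(self) -> np.ndarray:
        c = self.latent_corr if self.latent_corr is not None else default_latent_corr()
        c = np.asarray(c, dtype=float)
        if c.shape != (5, 5):
            raise ValueError("latent_corr must be 5x5 over " + str(LATENT_VARS))
        if not np.allclose(c, c.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("latent_corr is not positive semi-definite")
        return c


def _hpt_pct(z: np.ndarray) -> np.ndarray:
    return np.minimum(1.5 * np.exp(0.9 * z), 100.0)


def _abeta_pct(z: np.ndarray) -> np.ndarray:
    return np.minimum(2.5 * np.exp(0.9 * z), 100.0)


def _si_scale(z: np.ndarray) -> np.ndarray:
    return expit(-0.7 + 0.35 * z)


def make_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort; bit-reproducible for a fixed seed.

    Each case draws a 5-variate latent Gaussian (age, HPtau, Abeta, SI, WMH)
    with the configured correlation; AD cases receive the per-variable mean
    shifts.  Case-level latents map monotonically to observable scales
    (percent burdens, SI in (0, 1)); per-region values add regional noise to
    the case latent and the regional WMH latents discretize through the
    ARWMC cutpoints.  Latent columns are retained for calibration checks.
    """
    corr = config.corr()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_ad = int(round(n * config.prop_ad))
    is_ad = np.zeros(n, dtype=bool)
    is_ad[:n_ad] = True

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
    z = rng.standard_normal((n, 5)) @ chol.T
    shift = np.asarray(config.group_shift, dtype=float)
    z = z + np.where(is_ad[:, None], shift[None, :], 0.0)

    df = pd.DataFrame({
        "case_id": [f"case{i:03d}" for i in range(n)],
        "group": np.where(is_ad, "AD", "control"),
    })
    for j, name in enumerate(LATENT_VARS):
        df[f"latent_{name}"] = z[:, j]

    df["age_at_death"] = np.round(84.4 + 7.7 * z[:, 0], 1)
    df["pmd_hours"] = np.round(np.abs(rng.normal(48.9, 23.4, size=n)), 1)
    mmse = np.where(is_ad,
                    np.round(4.33 + 3.9 * rng.standard_normal(n)),
                    np.round(28.0 + 2.09 * rng.standard_normal(n)))
    df["mmse"] = np.clip(mmse, 0, 30).astype(int)
    df["braak_stage"] = np.where(is_ad, 6, rng.choice(_CTRL_BRAAK, size=n)).astype(int)
    df["thal_phase"] = np.where(is_ad, 5, rng.choice(_CTRL_THAL, size=n)).astype(int)

    # totals: exact monotone transforms of the case-level latents
    df["hpt_total"] = _hpt_pct(z[:, 1])
    df["abeta_total"] = _abeta_pct(z[:, 2])
    df["si_total"] = _si_scale(z[:, 3])

    lam = math.sqrt(_REGION_LOADING)
    noise = math.sqrt(1.0 - _REGION_LOADING)
    cp = np.asarray(config.arwmc_cutpoints)
    arwmc_regional: dict[str, np.ndarray] = {}
    for region in REGIONS:
        eps = rng.standard_normal((n, 4))
        z_hpt = lam * z[:, 1] + noise * eps[:, 0]
        z_ab = lam * z[:, 2] + noise * eps[:, 1]
        z_si = lam * z[:, 3] + noise * eps[:, 2]
        z_wmh = lam * z[:, 4] + noise * eps[:, 3]
        df[f"hpt_{region}"] = _hpt_pct(z_hpt)
        df[f"abeta_{region}"] = _abeta_pct(z_ab)
        df[f"si_{region}"] = _si_scale(z_si)
        score = np.digitize(z_wmh, cp)
        df[f"arwmc_{region}"] = score.astype(int)
        arwmc_regional[region] = score

    po = np.maximum(arwmc_regional["parietal"], arwmc_regional["occipital"])
    df["arwmc_parieto_occipital"] = po.astype(int)
    df["arwmc_total"] = (arwmc_regional["frontal"] + arwmc_regional["temporal"] + po) / 3.0
    return df
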