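"""Percent-area quantification of DAB immunoreactivity from RGB rasters.

The measurement chain mirrors routine chromogen quantification on captured
brightfield fields: an inclusive RGB box classifies each pixel as
immunopositive or not, an optional physical-size filter removes small
connected components (used for the amyloid marker to exclude physiological
APP staining), and the surviving positive area is expressed as a percentage
of the measured area.  Regions of interest may be excluded (white matter,
meninges); exclusion removes pixels from both numerator and denominator.

Aggregation follows a fixed cortical sampling plan of 24 locations per case
across six sections, reduced to four regional means (frontal, temporal,
parietal, occipital) and a hemisphere-wide total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "RGBThresholdSpec",
    "AT8_THRESHOLDS",
    "FOUR_G8_THRESHOLDS",
    "MontageImage",
    "IRResult",
    "SECTIONS",
    "REGION_SECTIONS",
    "default_sampling_plan",
    "classify_pixels",
    "filter_components",
    "percent_area",
    "aggregate_case",
]


@dataclass(frozen=True)
class RGBThresholdSpec:
    """Inclusive RGB box defining immunopositivity, plus an optional size filter.

    A pixel is positive iff each of its R, G, B values lies inside the
    corresponding inclusive range.  ``min_component_area`` (um^2) removes
    connected components strictly smaller than the threshold; ``None``
    disables the filter.
    """

    r_range: tuple[int, int]
    g_range: tuple[int, int]
    b_range: tuple[int, int]
    min_component_area: Optional[float] = None
    marker: str = ""

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("r_range", self.r_range),
            ("g_range", self.g_range),
            ("b_range", self.b_range),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 255, got ({lo}, {hi})")
        if self.min_component_area is not None and self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0 when present")


#: Tau marker (AT8) thresholds; no size restriction.
AT8_THRESHOLDS = RGBThresholdSpec((25, 170), (27, 156), (11, 126), None, marker="AT8")

#: Amyloid marker (4G8) thresholds; sub-100 um^2 signals (physiological APP)
#: are excluded by the size filter.
FOUR_G8_THRESHOLDS = RGBThresholdSpec((50, 180), (20, 168), (8, 139), 100.0, marker="4G8")

DEFAULT_THRESHOLDS: Mapping[str, RGBThresholdSpec] = {
    "AT8": AT8_THRESHOLDS,
    "4G8": FOUR_G8_THRESHOLDS,
}


@dataclass
class MontageImage:
    """An 8-bit RGB field with physical pixel scale and optional ROI exclusion.

    ``exclusion_mask`` marks pixels (True) that are removed from the measured
    area entirely — they can never be positive and do not count in the
    denominator.
    """

    rgb: np.ndarray
    pixel_size: Optional[float]  # um per pixel
    exclusion_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.size == 0:
            raise ValueError("rgb must be a nonempty (H, W, 3) array")
        if rgb.dtype != np.uint8:
            raise ValueError("rgb must be 8-bit (uint8)")
        self.rgb = rgb
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.exclusion_mask is not None:
            excl = np.asarray(self.exclusion_mask, dtype=bool)
            if excl.shape != rgb.shape[:2]:
                raise ValueError("exclusion_mask shape must match image")
            self.exclusion_mask = excl

    @property
    def n_pixels(self) -> int:
        return int(self.rgb.shape[0] * self.rgb.shape[1])


@dataclass(frozen=True)
class IRResult:
    """Immunoreactivity of one sample location: percent positive area."""

    percent_area: float
    positive_px: int
    measured_px: int
    marker: str

    def __post_init__(self) -> None:
        if self.positive_px > self.measured_px:
            raise ValueError("positive_px cannot exceed measured_px")
        expected = 100.0 * self.positive_px / self.measured_px
        if abs(self.percent_area - expected) > 1e-9:
            raise ValueError("percent_area inconsistent with pixel counts")


SECTIONS = ("prefrontal", "midfrontal", "entorhinal", "temporal", "parietal", "occipital")
LOCATION_CLASSES = ("sulcus", "midsection", "gyrus")

#: Regional means pool these sections (temporal includes the entorhinal cortex).
REGION_SECTIONS: Mapping[str, tuple[str, ...]] = {
    "frontal": ("prefrontal", "midfrontal"),
    "temporal": ("entorhinal", "temporal"),
    "parietal": ("parietal",),
    "occipital": ("occipital",),
}
REGIONS = tuple(REGION_SECTIONS)


def default_sampling_plan() -> list[tuple[str, str]]:
    """The 24-location cortical sampling plan: 4 locations per section.

    Each of the six sections contributes one sulcus, two midsection and one
    gyral-tip location, reflecting the sulcus-to-gyrus gradient of aggregate
    burden.
    """
    plan: list[tuple[str, str]] = []
    for section in SECTIONS:
        plan.extend(
            [(section, "sulcus"), (section, "midsection"), (section, "midsection"), (section, "gyrus")]
        )
    return plan


def classify_pixels(image: MontageImage, spec: RGBThresholdSpec) -> np.ndarray:
    """Classify pixels by the inclusive RGB box; returns a boolean mask.

    ROI-excluded pixels are never positive.  Raises if a size filter is
    configured but the image carries no pixel scale (the filter downstream
    would be meaningless).
    """
    if spec.min_component_area is not None and image.pixel_size is None:
        raise ValueError(
            "image has no pixel scale but the threshold spec requests a "
            f"{spec.min_component_area} um^2 size filter"
        )
    r = image.rgb[..., 0]
    g = image.rgb[..., 1]
    b = image.rgb[..., 2]
    (rl, rh), (gl, gh), (bl, bh) = spec.r_range, spec.g_range, spec.b_range
    mask = (
        (r >= rl) & (r <= rh)
        & (g >= gl) & (g <= gh)
        & (b >= bl) & (b <= bh)
    )
    if image.exclusion_mask is not None:
        mask &= ~image.exclusion_mask
    return mask


def filter_components(
    mask: np.ndarray, min_area_um2: float, pixel_size: float
) -> np.ndarray:
    """Remove 8-connected components strictly smaller than ``min_area_um2``.

    Components whose physical area (pixel count x pixel_size^2) is >= the
    threshold pass through untouched.  Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area_um2 <= 0:
        return mask.copy()
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("a positive pixel_size is required for the size filter")
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    px_area = pixel_size * pixel_size
    keep = counts * px_area >= min_area_um2
    keep[0] = False
    return keep[labels]


def percent_area(mask: np.ndarray, image: MontageImage, marker: str = "") -> IRResult:
    """Express surviving positive area as a percentage of the measured area.

    The measured area excludes ROI-excluded pixels.  Raises on a fully
    excluded field (zero measured pixels).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.rgb.shape[:2]:
        raise ValueError("mask shape must match image")
    if image.exclusion_mask is not None:
        measured = int(image.n_pixels - image.exclusion_mask.sum())
        positive = int((mask & ~image.exclusion_mask).sum())
    else:
        measured = image.n_pixels
        positive = int(mask.sum())
    if measured == 0:
        raise ValueError("zero measured pixels: the entire field is ROI-excluded")
    return IRResult(100.0 * positive / measured, positive, measured, marker)


def quantify(image: MontageImage, spec: RGBThresholdSpec) -> IRResult:
    """Full per-field chain: classify -> size-filter -> percent area."""
    mask = classify_pixels(image, spec)
    if spec.min_component_area is not None:
        mask = filter_components(mask, spec.min_component_area, image.pixel_size)
    return percent_area(mask, image, marker=spec.marker)


def aggregate_case(
    per_location: pd.DataFrame | Iterable[tuple[str, float]],
) -> dict[str, float]:
    """Reduce per-location percent areas to regional means and a total.

    ``per_location`` is a DataFrame with columns ``section`` and
    ``percent_area`` (or an iterable of (section, percent_area) pairs).
    Frontal pools the prefrontal and midfrontal locations, temporal pools the
    entorhinal and temporal locations; the total is the mean of the four
    regional means.  Raises if any section is absent, naming the missing ones.
    """
    if not isinstance(per_location, pd.DataFrame):
        per_location = pd.DataFrame(per_location, columns=["section", "percent_area"])
    present = set(per_location["section"])
    missing = [s for s in SECTIONS if s not in present]
    if missing:
        raise ValueError(f"sampling plan incomplete; missing sections: {', '.join(missing)}")
    unknown = present - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown sections: {sorted(unknown)}")
    out: dict[str, float] = {}
    for region, sections in REGION_SECTIONS.items():
        vals = per_location.loc[per_location["section"].isin(sections), "percent_area"]
        out[region] = float(vals.mean())
    out["total"] = float(np.mean([out[r] for r in REGIONS]))
    return out
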