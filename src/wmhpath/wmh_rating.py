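"""ARWMC-style rating of white-matter lesion masks.

Regional white-matter-hyperintensity severity is expressed on the 0-3
age-related white matter change (ARWMC) ordinal: 0 = no lesions,
1 = punctate (all lesions < 10 mm), 2 = early confluent (a lesion of
10-20 mm, or multiple 10-20 mm lesions joined by thin connecting bridges),
3 = confluent (a lesion > 20 mm).  Here a binary lesion mask with a mm
scale stands in for the rated T2 hyperintensity: each connected component
is sized by its maximum caliper (Feret) diameter, and thin bridges are
detected by an erosion split so that bridged early-confluent complexes are
not mistaken for single confluent lesions.

Regional scores are combined as in the hemisphere-wide protocol: parietal
and occipital collapse to a single parieto-occipital score, and the total
is the mean of the frontal, temporal and parieto-occipital scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure, morphology
from scipy import ndimage

__all__ = [
    "LesionComponent",
    "LesionCensus",
    "census_lesions",
    "feret_diameter_px",
    "score_region",
    "combine_scores",
    "BRIDGE_WIDTH_MM",
]

#: A connection narrower than this is a "bridge" between lesion lobes.
BRIDGE_WIDTH_MM = 3.0

PUNCTATE_LIMIT_MM = 10.0
CONFLUENT_LIMIT_MM = 20.0


@dataclass(frozen=True)
class LesionComponent:
    """One connected lesion: overall caliper size and any bridge decomposition."""

    diameter_mm: float
    lobe_diameters_mm: tuple[float, ...] = ()

    @property
    def bridged(self) -> bool:
        return len(self.lobe_diameters_mm) >= 2


@dataclass(frozen=True)
class LesionCensus:
    """All lesion components found in one regional mask."""

    components: tuple[LesionComponent, ...]

    def __len__(self) -> int:
        return len(self.components)

    @property
    def diameters_mm(self) -> tuple[float, ...]:
        return tuple(c.diameter_mm for c in self.components)


def feret_diameter_px(coords: np.ndarray) -> float:
    """Maximum pairwise distance between pixel centres of a component.

    Uses the convex hull for anything beyond a handful of points; identical
    to the brute-force all-pairs maximum.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 1:
        return 0.0
    if len(coords) > 4:
        try:
            hull = ConvexHull(coords)
            coords = coords[hull.vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    return float(pdist(coords).max())


def _split_lobes(component: np.ndarray, erosion_radius_px: int) -> list[np.ndarray]:
    """Erode a component; if it splits, recover its lobes.

    The component is probed with a disk of half the bridge-width limit: any
    connection thinner than the bridge limit erodes away.  Each surviving
    fragment is dilated back by the same probe within the component
    (a reconstructive opening), recovering the lobe's own extent without the
    bridge.  Returns an empty list when the component does not split.
    """
    if erosion_radius_px < 1:
        return []
    probe = morphology.disk(erosion_radius_px)
    eroded = morphology.erosion(component, probe)
    seeds, n_seeds = ndimage.label(eroded, structure=np.ones((3, 3)))
    if n_seeds < 2:
        return []
    return [
        morphology.dilation(seeds == i, probe) & component
        for i in range(1, n_seeds + 1)
    ]


def census_lesions(mask: np.ndarray, mm_per_px: float) -> LesionCensus:
    """Enumerate lesion components with caliper diameters and bridge lobes.

    8-connectivity.  An empty mask yields an empty census.  Bridge detection
    erodes each component by half the bridge-width limit; components that
    split are additionally described by their per-lobe caliper diameters.
    """
    mask = np.asarray(mask, dtype=bool)
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    labels = measure.label(mask, connectivity=2)
    comps: list[LesionComponent] = []
    erosion_radius_px = int(round((BRIDGE_WIDTH_MM / 2.0) / mm_per_px))
    for i in range(1, labels.max() + 1):
        comp = labels == i
        coords = np.argwhere(comp)
        diam = feret_diameter_px(coords) * mm_per_px
        lobe_diams: tuple[float, ...] = ()
        lobes = _split_lobes(comp, erosion_radius_px)
        if lobes:
            lobe_diams = tuple(
                feret_diameter_px(np.argwhere(lb)) * mm_per_px for lb in lobes
            )
        comps.append(LesionComponent(diam, lobe_diams))
    return LesionCensus(tuple(comps))


def score_region(census: LesionCensus) -> int:
    """ARWMC score (0-3) of one regional lesion census.

    0: no lesions.  1: all lesions punctate (< 10 mm).  2: early confluent —
    a lesion of 10-20 mm inclusive, or a bridged complex whose lobes all fall
    in 10-20 mm.  3: confluent — a lesion (or a lobe of a bridged complex)
    larger than 20 mm.  A bridged complex is sized by its lobes, not its
    overall span, so that thin bridges do not promote early-confluent disease
    to confluent.
    """
    if len(census) == 0:
        return 0
    score = 1
    for comp in census.components:
        if comp.bridged:
            sizes = comp.lobe_diameters_mm
        else:
            sizes = (comp.diameter_mm,)
        if any(d > CONFLUENT_LIMIT_MM for d in sizes):
            return 3
        if any(PUNCTATE_LIMIT_MM <= d <= CONFLUENT_LIMIT_MM for d in sizes):
            score = max(score, 2)
    return score


def combine_scores(
    frontal: int,
    temporal: int,
    parietal: int,
    occipital: int,
    parieto_occipital_mode: Literal["max", "mean"] = "max",
) -> dict[str, float]:
    """Combine per-region scores into the reported regional set and total.

    The parietal and occipital scores collapse to one parieto-occipital score
    (the maximum by default; configurable to the mean).  The total is the
    mean of the frontal, temporal and parieto-occipital scores.
    """
    for name, s in (("frontal", frontal), ("temporal", temporal),
                    ("parietal", parietal), ("occipital", occipital)):
        if s is None:
            raise ValueError(f"missing region score: {name}")
        if int(s) != s or not (0 <= s <= 3):
            raise ValueError(f"{name} score must be an integer in 0..3, got {s}")
    if parieto_occipital_mode == "max":
        po = float(max(parietal, occipital))
    elif parieto_occipital_mode == "mean":
        po = (parietal + occipital) / 2.0
    else:
        raise ValueError("parieto_occipital_mode must be 'max' or 'mean'")
    total = (frontal + temporal + po) / 3.0
    return {
        "frontal": float(frontal),
        "temporal": float(temporal),
        "parieto_occipital": po,
        "total": total,
    }
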