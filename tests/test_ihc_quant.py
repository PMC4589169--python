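"""Unit tests for the RGB-box classifier, size filter and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmhpath.ihc_quant import (
    AT8_THRESHOLDS,
    FOUR_G8_THRESHOLDS,
    MontageImage,
    RGBThresholdSpec,
    SECTIONS,
    aggregate_case,
    classify_pixels,
    default_sampling_plan,
    filter_components,
    percent_area,
)

from conftest import image_from, solid_image


class TestClassifyPixels:
    @pytest.mark.parametrize(
        "color,expected",
        [
            ((100, 100, 60), True),   # inside the tau box on all channels
            ((200, 100, 60), False),  # red channel above 170
            ((25, 27, 11), True),     # inclusive lower corner
            ((170, 156, 126), True),  # inclusive upper corner
            ((24, 100, 60), False),   # one below the red low bound
            ((255, 255, 255), False), # white background
        ],
    )
    def test_at8_box_membership(self, color, expected):
        img = solid_image((4, 4), color)
        assert classify_pixels(img, AT8_THRESHOLDS).all() == expected

    def test_all_white_image_has_no_positives(self):
        img = solid_image((16, 16), (255, 255, 255))
        assert classify_pixels(img, FOUR_G8_THRESHOLDS).sum() == 0

    def test_roi_excluded_pixels_never_positive(self):
        rgb = np.full((8, 8, 3), 100, dtype=np.uint8)
        excl = np.zeros((8, 8), dtype=bool)
        excl[:4] = True
        img = image_from(rgb, exclusion=excl)
        mask = classify_pixels(img, AT8_THRESHOLDS)
        assert not mask[:4].any() and mask[4:].all()

    def test_size_filter_without_scale_errors(self):
        img = MontageImage(rgb=np.full((4, 4, 3), 100, np.uint8), pixel_size=None)
        with pytest.raises(ValueError, match="pixel scale"):
            classify_pixels(img, FOUR_G8_THRESHOLDS)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 30))
    def test_widening_ranges_never_loses_positives(self, seed, widen):
        rng = np.random.default_rng(seed)
        rgb = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
        img = image_from(rgb)
        base = RGBThresholdSpec((60, 140), (60, 140), (60, 140))
        wide = RGBThresholdSpec(
            (max(0, 60 - widen), min(255, 140 + widen)),
            (max(0, 60 - widen), min(255, 140 + widen)),
            (max(0, 60 - widen), min(255, 140 + widen)),
        )
        assert classify_pixels(img, wide).sum() >= classify_pixels(img, base).sum()


def _census_oracle(mask: np.ndarray, min_area_px: float) -> int:
    """Brute-force flood-fill census of components at/above a pixel-area cut."""
    mask = mask.copy()
    survivors = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0]:
                continue
            stack, comp = [(r0, c0)], []
            mask[r0, c0] = False
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                            mask[rr, cc] = False
                            stack.append((rr, cc))
            if len(comp) >= min_area_px:
                survivors += 1
    return survivors


class TestFilterComponents:
    def test_hundred_micron_rule_boundary(self):
        # one 99 um^2 blob and one 101 um^2 blob at 1 um/px
        mask = np.zeros((64, 64), dtype=bool)
        mask[0:9, 0:11] = True                  # 99 px
        mask[30:39, 0:11] = True                # 99 px ...
        mask[39, 0:2] = True                    # ... plus 2 -> 101 px
        out = filter_components(mask, 100.0, pixel_size=1.0)
        assert not out[0:9, 0:11].any()
        assert out[30:40].sum() == 101

    def test_zero_threshold_is_identity(self, rng):
        mask = rng.random((32, 32)) < 0.3
        assert np.array_equal(filter_components(mask, 0.0, 1.0), mask)

    def test_idempotent(self, rng):
        mask = rng.random((48, 48)) < 0.35
        once = filter_components(mask, 9.0, pixel_size=1.0)
        twice = filter_components(once, 9.0, pixel_size=1.0)
        assert np.array_equal(once, twice)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    @pytest.mark.parametrize("pixel_size", [1.0, 2.0])
    def test_survivor_count_matches_flood_fill_oracle(self, seed, pixel_size):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.25
        min_area_um2 = 40.0
        out = filter_components(mask, min_area_um2, pixel_size)
        from skimage import measure
        n_out = measure.label(out, connectivity=2).max()
        assert n_out == _census_oracle(mask, min_area_um2 / pixel_size**2)

    def test_raising_threshold_never_adds_pixels(self, rng):
        mask = rng.random((40, 40)) < 0.3
        prev = mask.sum()
        for cut in (2.0, 5.0, 9.0, 20.0):
            out = filter_components(mask, cut, 1.0)
            assert out.sum() <= prev
            prev = out.sum()


class TestPercentArea:
    def test_basic_arithmetic(self):
        img = solid_image((10, 20), (255, 255, 255))
        mask = np.zeros((10, 20), dtype=bool)
        mask.ravel()[:50] = True
        res = percent_area(mask, img)
        assert res.percent_area == 25.0
        assert (res.positive_px, res.measured_px) == (50, 200)

    def test_exclusion_shrinks_denominator(self):
        rgb = np.full((10, 10, 3), 255, np.uint8)
        excl = np.zeros((10, 10), dtype=bool)
        excl[:, :5] = True
        img = image_from(rgb, exclusion=excl)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, 5:7] = True  # 20 positive of 50 measured
        res = percent_area(mask, img)
        assert res.percent_area == 40.0 and res.measured_px == 50

    def test_fully_excluded_field_errors(self):
        rgb = np.full((4, 4, 3), 255, np.uint8)
        img = image_from(rgb, exclusion=np.ones((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="excluded"):
            percent_area(np.zeros((4, 4), dtype=bool), img)


class TestAggregateCase:
    def test_sampling_plan_has_24_locations_all_sections(self):
        plan = default_sampling_plan()
        assert len(plan) == 24
        assert {s for s, _ in plan} == set(SECTIONS)

    def test_constant_values_pass_through(self):
        rows = [(s, 2.0) for s, _ in default_sampling_plan()]
        agg = aggregate_case(rows)
        assert all(v == 2.0 for v in agg.values())

    def test_total_is_mean_of_regional_means(self):
        rows = (
            [("prefrontal", 1.0), ("midfrontal", 1.0)]
            + [("entorhinal", 2.0), ("temporal", 2.0)]
            + [("parietal", 3.0), ("occipital", 4.0)]
        )
        agg = aggregate_case(rows)
        assert agg["frontal"] == 1.0 and agg["temporal"] == 2.0
        assert agg["total"] == pytest.approx(2.5)

    def test_random_table_matches_hand_recomputation(self, rng):
        plan = default_sampling_plan()
        vals = rng.uniform(0, 30, size=len(plan))
        rows = [(s, v) for (s, _), v in zip(plan, vals)]
        agg = aggregate_case(rows)
        # independent recomputation with plain python
        by_sec = {}
        for (s, _), v in zip(plan, vals):
            by_sec.setdefault(s, []).append(v)
        frontal = sum(by_sec["prefrontal"] + by_sec["midfrontal"]) / 8
        temporal = sum(by_sec["entorhinal"] + by_sec["temporal"]) / 8
        parietal = sum(by_sec["parietal"]) / 4
        occipital = sum(by_sec["occipital"]) / 4
        assert agg["frontal"] == pytest.approx(frontal)
        assert agg["temporal"] == pytest.approx(temporal)
        assert agg["total"] == pytest.approx((frontal + temporal + parietal + occipital) / 4)

    def test_missing_section_error_names_it(self):
        rows = [("prefrontal", 1.0), ("midfrontal", 1.0)]
        with pytest.raises(ValueError, match="entorhinal"):
            aggregate_case(rows)
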