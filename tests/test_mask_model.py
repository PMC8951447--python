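"""Mask family: sampling conformance, rasterization accuracy against
brute-force and analytic oracles, and summary statistics."""

from __future__ import annotations

import numpy as np
import pytest

from irisynth.mask_model import (
    ConditionPair,
    MaskParameters,
    ParameterRanges,
    fit_parameter_statistics,
    load_parameters_csv,
    make_condition_pair,
    rasterize_iris_mask,
    rasterize_periocular_mask,
    sample_parameters,
    save_parameters_csv,
)

CENTERED = MaskParameters(
    pupil_x=320, pupil_y=240, pupil_r=40,
    iris_x=320, iris_y=240, iris_r=100,
    x_offset=0, y_offset=0, x_ratio=1.8, y_ratio=0.8, degree=0,
)


def brute_force_annulus(params: MaskParameters, shape) -> np.ndarray:
    """Per-pixel loop oracle for the annulus inequality."""
    h, w = shape
    out = np.zeros(shape, dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            din = (x - params.iris_x) ** 2 + (y - params.iris_y) ** 2
            dpu = (x - params.pupil_x) ** 2 + (y - params.pupil_y) ** 2
            out[y, x] = int(din <= params.iris_r**2 and dpu > params.pupil_r**2)
    return out


def brute_force_ellipse(params: MaskParameters, shape) -> np.ndarray:
    """Per-pixel loop oracle for the rotated-ellipse inequality."""
    h, w = shape
    cx, cy = params.ellipse_center
    a, b = params.semi_axes
    th = np.deg2rad(params.degree)
    out = np.zeros(shape, dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            u = (x - cx) * np.cos(th) + (y - cy) * np.sin(th)
            v = -(x - cx) * np.sin(th) + (y - cy) * np.cos(th)
            out[y, x] = int((u / a) ** 2 + (v / b) ** 2 <= 1.0)
    return out


class TestSampling:
    def test_identical_seed_identical_parameters(self):
        assert sample_parameters(seed=42) == sample_parameters(seed=42)

    def test_draws_respect_all_intervals_and_containment(self):
        ranges = ParameterRanges()
        root = np.random.SeedSequence(0)
        for child in root.spawn(1000):
            p = sample_parameters(ranges, np.random.default_rng(child))
            assert ranges.pupil_r[0] <= p.pupil_r <= ranges.pupil_r[1]
            assert ranges.iris_r[0] <= p.iris_r <= ranges.iris_r[1]
            assert ranges.x_ratio[0] <= p.x_ratio <= ranges.x_ratio[1]
            assert ranges.y_ratio[0] <= p.y_ratio <= ranges.y_ratio[1]
            assert ranges.degree[0] <= p.degree <= ranges.degree[1]
            assert abs(p.x_offset) <= p.x_ratio * p.iris_r / 2
            assert abs(p.y_offset) <= p.y_ratio * p.iris_r / 2
            assert ranges.center_x[0] <= p.iris_x <= ranges.center_x[1]
            # containment: pupil disc inside iris disc
            d = np.hypot(p.pupil_x - p.iris_x, p.pupil_y - p.iris_y)
            assert d + p.pupil_r <= p.iris_r + 1e-9

    def test_impossible_ranges_raise(self):
        bad = ParameterRanges(pupil_r=(80.0, 90.0), iris_r=(70.0, 75.0))
        with pytest.raises(ValueError):
            sample_parameters(bad, seed=0)

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError, match="lower > upper"):
            sample_parameters(ParameterRanges(degree=(15.0, -15.0)), seed=0)


class TestParameterInvariants:
    def test_pupil_outside_iris_rejected(self):
        with pytest.raises(ValueError, match="contained"):
            MaskParameters(400, 240, 40, 320, 240, 100, 0, 0, 1.8, 0.8, 0).validate()

    def test_pupil_radius_must_be_smaller(self):
        with pytest.raises(ValueError, match="smaller"):
            MaskParameters(320, 240, 100, 320, 240, 100, 0, 0, 1.8, 0.8, 0).validate()


class TestRasterization:
    def test_annulus_matches_brute_force_oracle(self):
        params = MaskParameters(40, 36, 12, 42, 38, 30, 2, -3, 1.5, 0.7, 10)
        got = rasterize_iris_mask(params, (80, 90))
        assert np.array_equal(got, brute_force_annulus(params, (80, 90)))

    def test_ellipse_matches_brute_force_oracle(self):
        params = MaskParameters(40, 36, 12, 42, 38, 30, 5, -4, 1.4, 0.6, -12)
        got = rasterize_periocular_mask(params, (80, 90))
        assert np.array_equal(got, brute_force_ellipse(params, (80, 90)))

    def test_annulus_area_close_to_analytic(self):
        mask = rasterize_iris_mask(CENTERED)
        expected = np.pi * (100**2 - 40**2)
        assert abs(mask.sum() - expected) / expected < 0.01

    def test_ellipse_area_close_to_analytic(self):
        mask = rasterize_periocular_mask(CENTERED)
        a, b = CENTERED.semi_axes
        expected = np.pi * a * b
        assert abs(mask.sum() - expected) / expected < 0.01

    def test_degenerate_annulus_nearly_empty(self):
        p = MaskParameters(320, 240, 99.9, 320, 240, 100, 0, 0, 1.8, 0.8, 0)
        assert rasterize_iris_mask(p).sum() < 0.02 * np.pi * 100**2

    def test_partially_out_of_frame_clips_without_error(self):
        p = MaskParameters(10, 10, 30, 10, 10, 90, 0, 0, 1.8, 0.8, 0)
        mask = rasterize_iris_mask(p, (100, 100))
        assert mask.shape == (100, 100)
        assert 0 < mask.sum() < np.pi * 90**2

    def test_rotation_90_with_swapped_axes_matches_unrotated(self):
        base = MaskParameters(320, 240, 40, 320, 240, 100, 0, 0, 1.6, 0.8, 0)
        # swapped semi-axes, rotated a quarter turn
        swapped = MaskParameters(320, 240, 40, 320, 240, 100, 0, 0, 0.8, 1.6, 90)
        a = rasterize_periocular_mask(base)
        b = rasterize_periocular_mask(swapped)
        # a handful of exactly-on-boundary pixels may flip under the
        # epsilon-sized rotation residue of cos(90 deg)
        assert (a != b).mean() < 1e-4

    def test_circle_is_rotation_invariant(self):
        a = MaskParameters(320, 240, 40, 320, 240, 100, 0, 0, 1.2, 1.2, 0)
        b = MaskParameters(320, 240, 40, 320, 240, 100, 0, 0, 1.2, 1.2, 13)
        assert np.array_equal(rasterize_periocular_mask(a), rasterize_periocular_mask(b))

    def test_non_positive_resolution_raises(self):
        with pytest.raises(ValueError, match="positive"):
            rasterize_iris_mask(CENTERED, (0, 640))


class TestConditionPair:
    def test_shapes_and_binarity(self):
        pair = make_condition_pair(CENTERED)
        assert pair.iris_mask.shape == pair.periocular_mask.shape == (256, 256)
        assert set(np.unique(pair.iris_mask)) <= {0, 1}
        assert set(np.unique(pair.periocular_mask)) <= {0, 1}

    def test_deterministic_across_calls(self):
        a = make_condition_pair(CENTERED)
        b = make_condition_pair(CENTERED)
        assert np.array_equal(a.iris_mask, b.iris_mask)
        assert np.array_equal(a.periocular_mask, b.periocular_mask)

    def test_clipping_confines_iris_to_periocular(self):
        # a small, low ellipse that cuts the annulus
        p = MaskParameters(320, 240, 40, 320, 240, 100, 0, 0, 1.5, 0.4, 0)
        pair = make_condition_pair(p, clip_iris_to_periocular=True)
        outside = pair.iris_mask & (1 - pair.periocular_mask)
        assert outside.sum() == 0

    def test_mismatched_mask_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            ConditionPair(np.zeros((4, 4), np.uint8), np.zeros((5, 4), np.uint8))

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ConditionPair(np.full((4, 4), 2, np.uint8), np.zeros((4, 4), np.uint8))


class TestStatistics:
    def test_single_sample_degenerate_summary(self):
        table = fit_parameter_statistics([CENTERED])
        assert (table["std"] == 0).all()
        assert (table["average"] == table["min"]).all()
        assert (table["average"] == table["max"]).all()

    def test_symmetric_pair_mean(self):
        a = MaskParameters(320, 240, 30, 320, 240, 100, 0, 0, 1.8, 0.8, -10)
        b = MaskParameters(320, 240, 50, 320, 240, 100, 0, 0, 1.8, 0.8, 10)
        table = fit_parameter_statistics([a, b])
        assert table.loc["PupilR", "average"] == 40
        assert table.loc["Degree", "average"] == 0

    def test_uniform_draws_recover_interval_midpoint(self):
        ranges = ParameterRanges()
        root = np.random.SeedSequence(1)
        draws = [sample_parameters(ranges, np.random.default_rng(c)) for c in root.spawn(1000)]
        table = fit_parameter_statistics(draws)
        lo, hi = ranges.pupil_r
        se = (hi - lo) / np.sqrt(12) / np.sqrt(1000)
        assert abs(table.loc["PupilR", "average"] - (lo + hi) / 2) < 3 * se
        assert lo <= table.loc["PupilR", "min"]
        assert table.loc["PupilR", "max"] <= hi

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fit_parameter_statistics([])

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "params.csv"
        draws = [sample_parameters(seed=i) for i in range(5)]
        save_parameters_csv(draws, path)
        loaded = load_parameters_csv(path)
        for got, want in zip(loaded, draws):
            assert got.to_row() == pytest.approx(want.to_row(), rel=1e-12)
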