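import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from pahscape.grids import ConcentrationGrid
from pahscape.model import (
    GaussianFit,
    PeakFeatures,
    artifact_filter,
    extract_features,
    fit_gaussian,
    gaussian_surface,
    smooth_landscape,
    working_range,
)
from pahscape.pipeline import process_genotype
from pahscape.plates import ActivityLandscape
from pahscape.simulate import NoiseModel, simulate_plates, truth_surface


def _landscape(truth, grid):
    return ActivityLandscape("G", truth_surface(truth, grid, raw_units=False), "percent_wt", grid)


class TestFitGaussian:
    def test_exact_model_recovery(self, canonical_truth, noiseless_landscape):
        """Noiseless model-generated data identifies all five parameters."""
        fit = fit_gaussian(noiseless_landscape)
        assert fit.converged
        t = canonical_truth
        for got, want in [
            (fit.a, t.a),
            (fit.mx_prime, t.mx_prime),
            (fit.my_prime, t.my_prime),
            (fit.sx_prime, t.sx_prime),
            (fit.sy_prime, t.sy_prime),
        ]:
            assert abs(got - want) / abs(want) <= 1e-4
        assert fit.rmse_fit == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_10_percent(self, canonical_truth, grid):
        rng = np.random.default_rng(42)
        z = truth_surface(canonical_truth, grid, raw_units=False)
        noisy = z * (1 + 0.05 * rng.standard_normal(grid.shape))
        fit = fit_gaussian(ActivityLandscape("G", np.clip(noisy, 0, None), "percent_wt", grid))
        assert fit.converged
        assert abs(fit.a - 50.0) / 50.0 < 0.10
        assert abs(math.exp(fit.mx_prime) - 330.0) / 330.0 < 0.10
        assert abs(math.exp(fit.my_prime) - 101.0) / 101.0 < 0.10

    def test_objective_beats_coarse_grid_search(self, grid):
        """The optimizer's SSE never exceeds a brute-force grid minimum."""
        truth = GaussianFit(20.0, math.log(150.0), math.log(50.0), 0.7, 0.8, True, 0.0)
        land = _landscape(truth, grid)
        fit = fit_gaussian(land)
        mask = grid.nonzero_mask()
        phe, bh4 = np.meshgrid(grid.phe, grid.bh4, indexing="ij")
        xp, yp = np.log(phe[mask]), np.log(bh4[mask])
        z = land.values[mask]

        def sse(a, mx, my, sx, sy):
            return float(np.sum((gaussian_surface(xp, yp, a, mx, my, sx, sy) - z) ** 2))

        best = min(
            sse(a, mx, my, sx, sy)
            for a in (10.0, 20.0, 30.0)
            for mx in np.log((100.0, 150.0, 250.0))
            for my in np.log((25.0, 50.0, 75.0))
            for sx in (0.5, 0.7, 1.0)
            for sy in (0.6, 0.8, 1.0)
        )
        assert sse(fit.a, fit.mx_prime, fit.my_prime, fit.sx_prime, fit.sy_prime) <= best + 1e-9

    def test_all_zero_landscape_does_not_converge(self, grid):
        fit = fit_gaussian(ActivityLandscape("G", np.zeros(grid.shape), "percent_wt", grid))
        assert not fit.converged
        assert fit.a == 0.0

    def test_scale_equivariance(self, canonical_truth, noiseless_landscape, grid):
        fit1 = fit_gaussian(noiseless_landscape)
        fit3 = fit_gaussian(
            ActivityLandscape("G", 3.0 * noiseless_landscape.values, "percent_wt", grid)
        )
        assert fit3.a == pytest.approx(3.0 * fit1.a, rel=1e-6)
        for attr in ("mx_prime", "my_prime", "sx_prime", "sy_prime"):
            assert getattr(fit3, attr) == pytest.approx(getattr(fit1, attr), rel=1e-6)


class TestWorkingRange:
    def test_closed_form_matches_numeric_root_finding(self, canonical_truth):
        fit = canonical_truth
        low, high = working_range(fit)

        def f(xp):
            return gaussian_surface(np.array(xp), np.array(fit.my_prime), fit.a, fit.mx_prime, fit.my_prime, fit.sx_prime, fit.sy_prime) - fit.a / 2

        low_num = math.exp(brentq(f, fit.mx_prime - 6 * fit.sx_prime, fit.mx_prime, xtol=1e-14))
        high_num = math.exp(brentq(f, fit.mx_prime, fit.mx_prime + 6 * fit.sx_prime, xtol=1e-14))
        assert abs(low - low_num) / low_num <= 1e-9
        assert abs(high - high_num) / high_num <= 1e-9

    def test_degenerate_width_collapses_to_peak(self):
        fit = GaussianFit(10.0, math.log(330.0), math.log(101.0), 1e-12, 0.9, True, 0.0)
        low, high = working_range(fit)
        assert low == pytest.approx(330.0, rel=1e-6)
        assert high == pytest.approx(330.0, rel=1e-6)

    def test_wild_type_range_spans_80_to_about_1372(self):
        """The WT working range 80-1372 uM [Phe] follows from peak 330 and sx'."""
        sx = math.log(330.0 / 80.0) / math.sqrt(2 * math.log(2))
        fit = GaussianFit(100.0, math.log(330.0), math.log(101.0), sx, 0.9, True, 0.0)
        low, high = working_range(fit)
        assert low == pytest.approx(80.0, rel=1e-9)
        assert high == pytest.approx(330.0**2 / 80.0, rel=1e-9)
        assert 1265 <= high <= 1479  # consistent with 1372 +/- 107

    @given(
        mx=st.floats(min_value=math.log(20), max_value=math.log(2500)),
        sx=st.floats(min_value=0.05, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_geometric_symmetry(self, mx, sx):
        """low * high = peak^2: log-space symmetry of the half-maximum points."""
        fit = GaussianFit(10.0, mx, math.log(100.0), sx, 0.9, True, 0.0)
        low, high = working_range(fit)
        assert abs(low * high - math.exp(mx) ** 2) <= 1e-9 * math.exp(mx) ** 2


class TestSmoothLandscape:
    def test_identity_at_no_upsampling_no_smoothing(self, noiseless_landscape):
        dense, phe_d, bh4_d = smooth_landscape(noiseless_landscape, upsample=1, sigma=0.0)
        np.testing.assert_allclose(dense, noiseless_landscape.values)
        np.testing.assert_allclose(phe_d, noiseless_landscape.grid.phe)

    def test_constant_preserved(self, grid):
        land = ActivityLandscape("G", np.full(grid.shape, 4.2), "percent_wt", grid)
        dense, _, _ = smooth_landscape(land, upsample=3, sigma=1.5)
        np.testing.assert_allclose(dense, 4.2)

    def test_smoothed_argmax_near_raw_argmax(self, noiseless_landscape, grid):
        dense, phe_d, bh4_d = smooth_landscape(noiseless_landscape, upsample=4, sigma=1.0)
        i, j = np.unravel_index(np.argmax(dense), dense.shape)
        ri, rj = np.unravel_index(np.argmax(noiseless_landscape.values), grid.shape)
        # within one coarse cell of the raw argmax
        assert abs(phe_d[i] - grid.phe[ri]) <= np.diff(grid.phe).max()
        assert abs(bh4_d[j] - grid.bh4[rj]) <= np.diff(grid.bh4).max()


class TestFeaturesAndArtifactFilter:
    def test_self_normalization_gives_100_pct(self, canonical_truth, grid):
        f = extract_features(canonical_truth, canonical_truth, "G", grid=grid)
        assert f.activity_max_pct_wt == pytest.approx(100.0)
        assert f.has_peak

    def test_feature_arithmetic(self, canonical_truth, grid):
        fit = GaussianFit(0.08 * canonical_truth.a, math.log(330.0), math.log(101.0), 0.9, 0.9, True, 0.0)
        f = extract_features(fit, canonical_truth, "G", grid=grid)
        assert f.activity_max_pct_wt == pytest.approx(8.0)
        assert f.phe_peak_uM == pytest.approx(330.0)
        assert f.working_range_low_uM < f.phe_peak_uM < f.working_range_high_uM

    def test_artifact_filter_rules(self):
        def feats(phe, act, has_peak=True):
            return PeakFeatures("G", act, phe, 100.0, 50.0, 600.0, 550.0, has_peak, act)

        assert artifact_filter(feats(2000.0, 2.0)) is True
        assert artifact_filter(feats(330.0, 100.0)) is False
        # boundary: strict inequalities
        assert artifact_filter(feats(1500.0, 3.0)) is False
        assert artifact_filter(feats(1500.0 + 1e-9, 3.0 - 1e-9)) is True
        assert artifact_filter(feats(330.0, 5.0, has_peak=False)) is True

    def test_out_of_range_peak_judged_at_observed_level(self, grid):
        """A runaway extrapolated amplitude cannot defeat the artifact rule."""
        wt = GaussianFit(100.0, math.log(330.0), math.log(101.0), 1.2, 0.9, True, 0.0)
        runaway = GaussianFit(4.0, math.log(6000.0), math.log(101.0), 1.0, 0.9, True, 0.0)
        f = extract_features(runaway, wt, "G", grid=grid)
        assert f.activity_in_range_pct_wt < f.activity_max_pct_wt
        assert artifact_filter(f) is True
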