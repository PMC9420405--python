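"""RMA fitting, slope contrasts, intercept comparison and trajectory angles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from craniomorph.allometry import (
    centroid_angles,
    clarke_test,
    compare_intercepts,
    fit_rma,
    pairwise_slope_tests,
)
from craniomorph.errors import FitError


@pytest.fixture
def noisy_line():
    rng = np.random.default_rng(8)
    x = rng.normal(size=40)
    y = -1.5 * x + 0.4 + 0.5 * rng.normal(size=40)
    return x, y


class TestFitRMA:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_rma(x, 2 * x + 1, intercept_ci_method="analytic")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.p_r0 == 0.0

    def test_swapping_axes_inverts_the_slope(self, noisy_line):
        x, y = noisy_line
        fxy = fit_rma(x, y, intercept_ci_method="analytic")
        fyx = fit_rma(y, x, intercept_ci_method="analytic")
        assert fyx.slope == pytest.approx(1.0 / fxy.slope, abs=1e-12)

    def test_scaling_y_scales_slope(self, noisy_line):
        x, y = noisy_line
        base = fit_rma(x, y, intercept_ci_method="analytic").slope
        scaled = fit_rma(x, 3.0 * y, intercept_ci_method="analytic").slope
        assert scaled == pytest.approx(3.0 * base, abs=1e-12)

    def test_slope_sign_follows_correlation(self, noisy_line):
        x, y = noisy_line
        fit = fit_rma(x, y, intercept_ci_method="analytic")
        assert np.sign(fit.slope) == np.sign(fit.r) == -1

    @pytest.mark.parametrize("rep", range(5))
    def test_slope_minimizes_triangle_areas(self, rep):
        """The RMA line through the centroid minimizes the summed areas of
        the right triangles formed by each point with the line."""
        rng = np.random.default_rng(100 + rep)
        x = rng.normal(size=10)
        y = 1.7 * x + 0.6 * rng.normal(size=10)
        xc, yc = x - x.mean(), y - y.mean()

        def area(b):
            return np.sum((yc - b * xc) ** 2) / (2 * abs(b))

        best = minimize_scalar(area, bounds=(0.05, 50.0), method="bounded").x
        fit = fit_rma(x, y, intercept_ci_method="analytic")
        assert fit.slope == pytest.approx(best, rel=1e-4)

    def test_slope_ci_contains_slope_and_covers_truth(self, noisy_line):
        x, y = noisy_line
        fit = fit_rma(x, y, intercept_ci_method="analytic")
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_bootstrap_cis_are_seed_reproducible(self, noisy_line):
        x, y = noisy_line
        a = fit_rma(x, y, seed=5)
        b = fit_rma(x, y, seed=5)
        assert a.intercept_ci == b.intercept_ci

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError, match="n >= 3"):
            fit_rma([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(FitError, match="zero variance"):
            fit_rma([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClarke:
    def test_identical_fits_give_T_zero_p_one(self, noisy_line):
        x, y = noisy_line
        fit = fit_rma(x, y, intercept_ci_method="analytic")
        cmp = clarke_test(fit, fit)
        assert cmp.T == pytest.approx(0.0, abs=1e-12)
        assert cmp.p == pytest.approx(1.0)

    def test_symmetry(self, noisy_line):
        x, y = noisy_line
        rng = np.random.default_rng(9)
        x2 = rng.normal(size=25)
        y2 = -2.5 * x2 + rng.normal(size=25)
        a = fit_rma(x, y, intercept_ci_method="analytic")
        b = fit_rma(x2, y2, intercept_ci_method="analytic")
        assert clarke_test(a, b).p == pytest.approx(clarke_test(b, a).p, abs=1e-15)

    def test_opposite_sign_slopes_rejected(self, noisy_line):
        x, y = noisy_line
        a = fit_rma(x, y, intercept_ci_method="analytic")
        b = fit_rma(x, -y, intercept_ci_method="analytic")
        with pytest.raises(FitError, match="opposite signs"):
            clarke_test(a, b)

    def test_axis_identity_enforced(self, noisy_line):
        x, y = noisy_line
        a = fit_rma(x, y, x_label="f1", y_label="f2", intercept_ci_method="analytic")
        b = fit_rma(x, y, x_label="pls", y_label="f2", intercept_ci_method="analytic")
        with pytest.raises(FitError, match="different axes"):
            clarke_test(a, b)

    def test_type_one_error_is_calibrated(self, clarke_type1_rate):
        """Monte-Carlo size of the test at alpha = 5%: 2000 replicate pairs
        with equal true slopes at n = 50 each."""
        assert 0.035 <= clarke_type1_rate <= 0.065


class TestIntercepts:
    def test_disjoint_and_overlapping_intervals(self, noisy_line):
        x, y = noisy_line
        a = fit_rma(x, y, intercept_ci_method="analytic")
        b = fit_rma(x, y + 10.0, intercept_ci_method="analytic")
        c = fit_rma(x, y + 0.01, intercept_ci_method="analytic")
        assert not compare_intercepts(a, b).overlap
        assert compare_intercepts(a, c).overlap

    def test_bootstrap_interval_contains_point_intercept(self):
        """Across 1000 simulated line-plus-noise datasets, the bootstrap
        intercept interval should essentially always contain the analytic
        point estimate computed on the same data."""
        rng = np.random.default_rng(31)
        hits = 0
        trials = 1000
        for i in range(trials):
            x = rng.normal(size=25)
            y = 2.0 * x + 1.0 + 0.8 * rng.normal(size=25)
            fit = fit_rma(x, y, seed=i, n_boot=500)
            hits += fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]
        assert hits / trials >= 0.95


class TestCentroidAngles:
    def test_analytic_angle(self):
        scores = np.array([[0.0, 0.0], [-1.0, 1.0]])
        angles = centroid_angles(scores, ["g", "g"], ["juvenile", "adult"])
        assert angles["g"].angle_deg == pytest.approx(135.0)

    def test_matches_cosine_rule(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(30, 2))
        groups = np.repeat(["a", "b", "c"], 10)
        stages = np.tile(["juvenile"] * 5 + ["adult"] * 5, 3)
        angles = centroid_angles(scores, groups, stages)
        for g in ("a", "b", "c"):
            d = np.array(angles[g].adult_centroid) - np.array(angles[g].juvenile_centroid)
            cosine = d[0] / np.linalg.norm(d)
            assert angles[g].angle_deg == pytest.approx(
                np.degrees(np.arccos(np.clip(cosine, -1, 1))), abs=1e-9
            )

    def test_missing_stage_names_the_group(self):
        scores = np.zeros((4, 2))
        with pytest.raises(FitError, match="'b'"):
            centroid_angles(scores, ["a", "a", "b", "b"],
                            ["juvenile", "adult", "adult", "adult"])


def test_pairwise_matrix_is_symmetric_with_unit_diagonal(noisy_line):
    x, y = noisy_line
    rng = np.random.default_rng(21)
    fits = {
        "one": fit_rma(x, y, intercept_ci_method="analytic"),
        "two": fit_rma(x + rng.normal(size=40) * 0.1, y, intercept_ci_method="analytic"),
    }
    mat = pairwise_slope_tests(fits)
    assert mat.loc["one", "one"] == 1.0
    assert mat.loc["one", "two"] == mat.loc["two", "one"]
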