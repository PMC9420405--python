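"""Heterochrony decomposition, EQ, correlations and partial correlations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from craniomorph.allometry import RMAFit, fit_rma
from craniomorph.errors import FitError
from craniomorph.heterochrony import (
    compute_eq,
    correlations,
    decompose,
    ontogenetic_polarity,
    partial_correlation,
)


def line_fit(slope, intercept=0.0, n=10, r=None, sd_x=1.0):
    """Hand-built RMA fit for geometric tests (centroid at x = 0)."""
    r = r if r is not None else (1.0 if slope > 0 else -1.0)
    return RMAFit(
        slope=slope, intercept=intercept, r=r, n=n,
        slope_ci=(slope, slope), intercept_ci=(intercept, intercept),
        p_r0=0.0, mean_x=0.0, mean_y=intercept, sd_x=sd_x, sd_y=abs(slope) * sd_x,
    )


class TestDecompose:
    def test_target_at_reference_centroid(self):
        fit = line_fit(-3.0)
        u = np.array([1.0, -3.0]) / np.sqrt(10)
        d = decompose(fit, u, np.array([0.0, 0.0]), offset_threshold=0.5)
        assert d.along == pytest.approx(0.0, abs=1e-12)
        assert d.offset == pytest.approx(0.0, abs=1e-12)
        assert d.scaling_label == "none"
        assert d.transposition_label == "on-trajectory"

    def test_target_on_line_beyond_adult_state(self):
        """Line y = -3x through the origin, polarity toward +x; the target
        (1, -3) lies on the line one step past the centroid: pure
        peramorphic ontogenetic scaling."""
        fit = line_fit(-3.0)
        u = np.array([1.0, -3.0]) / np.sqrt(10)
        d = decompose(fit, u, np.array([1.0, -3.0]), offset_threshold=0.5)
        assert d.along == pytest.approx(np.sqrt(10.0))
        assert d.offset == pytest.approx(0.0, abs=1e-12)
        assert d.scaling_label == "peramorphic"
        assert d.transposition_label == "on-trajectory"

    def test_pythagoras_between_components(self):
        fit = line_fit(0.5)
        u = np.array([1.0, 0.5]) / np.sqrt(1.25)
        target = np.array([2.0, 3.0])
        d = decompose(fit, u, target, offset_threshold=0.5)
        assert d.along**2 + d.offset**2 == pytest.approx(
            np.sum((target - fit.centroid) ** 2), abs=1e-9
        )

    def test_rotation_equivariance(self):
        """Rotating the line, polarity and target together leaves the
        (along, offset) coordinates unchanged."""
        base_angle = np.arctan(0.75)
        target = np.array([1.3, -0.2])
        reference = decompose(
            line_fit(0.75), np.array([np.cos(base_angle), np.sin(base_angle)]),
            target, offset_threshold=1.0,
        )
        for rot in (0.1, -0.3, 0.7):
            angle = base_angle + rot
            if abs(np.cos(angle)) < 1e-3:
                continue
            R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
            fit = line_fit(np.tan(angle))
            d = decompose(
                fit, np.array([np.cos(angle), np.sin(angle)]), R @ target,
                offset_threshold=1.0,
            )
            assert d.along == pytest.approx(reference.along, abs=1e-9)
            assert d.offset == pytest.approx(reference.offset, abs=1e-9)

    def test_zero_polarity_rejected(self):
        with pytest.raises(FitError, match="non-zero"):
            decompose(line_fit(1.0), np.zeros(2), np.ones(2))

    def test_polarity_must_follow_the_line(self):
        with pytest.raises(FitError, match="parallel"):
            decompose(line_fit(1.0), np.array([1.0, -1.0]), np.ones(2))

    def test_recovers_known_transposition_offset(self):
        """Two parallel trajectories separated by a vertical shift delta:
        the mean recovered |offset| equals delta * cos(atan(slope)) within
        5% over 200 seeded replicates."""
        slope, delta = -2.0, 0.8
        expected = delta * np.cos(np.arctan(abs(slope)))
        rng = np.random.default_rng(55)
        offsets = []
        for _ in range(200):
            x = rng.normal(size=40)
            y = slope * x + 0.05 * rng.normal(size=40)
            fit = fit_rma(x, y, intercept_ci_method="analytic")
            u = fit.direction
            xt = rng.normal(size=20)
            yt = slope * xt + delta + 0.05 * rng.normal(size=20)
            target = np.array([xt.mean(), yt.mean()])
            offsets.append(abs(decompose(fit, u, target).offset))
        assert np.mean(offsets) == pytest.approx(expected, rel=0.05)

    def test_polarity_helper_points_toward_adults(self):
        fit = line_fit(-3.0)
        juv, adu = np.array([1.0, -3.0]), np.array([-1.0, 3.0])
        u = ontogenetic_polarity(juv, adu, fit)
        assert u @ (adu - juv) > 0
        np.testing.assert_allclose(np.abs(u), np.abs(fit.direction), atol=1e-12)


class TestEncephalization:
    def test_unit_constants_identity(self):
        rec = compute_eq(bm_kg=[2.0, 3.0], ecv_cm3=[2.0, 3.0], a=1.0, b=1.0)
        np.testing.assert_allclose(rec.eq, 1.0)

    def test_joint_scaling_invariance(self):
        base = compute_eq([50.0], [400.0], a=1.77, b=0.76)
        scaled = compute_eq([50.0], [400.0 * 3], a=1.77 * 3, b=0.76)
        np.testing.assert_allclose(scaled.eq, base.eq)

    def test_rank_order_matches_independent_computation(self):
        rng = np.random.default_rng(3)
        bm = rng.uniform(20, 90, size=15)
        ecv = rng.uniform(300, 1500, size=15)
        rec = compute_eq(bm, ecv, a=1.77, b=0.76)
        independent = ecv / bm**0.76
        assert list(np.argsort(rec.eq)) == list(np.argsort(independent))

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(FitError):
            compute_eq([0.0], [100.0])


class TestCorrelations:
    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(17)
        table = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        res = correlations(table)
        for u in table.columns:
            assert res.correlation_matrix.loc[u, u] == 1.0
            for v in table.columns:
                xu = table[u] - table[u].mean()
                xv = table[v] - table[v].mean()
                direct = (xu * xv).sum() / np.sqrt((xu**2).sum() * (xv**2).sum())
                assert res.correlation_matrix.loc[u, v] == pytest.approx(direct, abs=1e-12)

    def test_too_few_complete_cases_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan], "b": [2.0, 1.0, 4.0, 5.0]})
        with pytest.raises(FitError, match="4 complete"):
            correlations(table)

    def test_groupby_splits_independently(self):
        rng = np.random.default_rng(23)
        table = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        table["grp"] = np.repeat(["one", "two"], 20)
        per_group = correlations(table, groupby="grp")
        direct = correlations(table.loc[table.grp == "one", ["a", "b"]])
        assert per_group["one"].correlation_matrix.equals(direct.correlation_matrix)


class TestPartialCorrelation:
    def test_orthogonal_control_changes_nothing(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        z = rng.normal(size=50)
        # orthogonalize z against x and y in-sample so r_xz = r_yz = 0
        design = np.column_stack([np.ones(50), x, y])
        z = z - design @ np.linalg.lstsq(design, z, rcond=None)[0]
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_equals_residual_correlation(self):
        rng = np.random.default_rng(31)
        z = rng.normal(size=40)
        x = 0.8 * z + rng.normal(size=40)
        y = -0.5 * z + rng.normal(size=40)
        res = partial_correlation(x, y, z)
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_symmetry_in_x_and_y(self):
        rng = np.random.default_rng(37)
        x, y, z = rng.normal(size=(3, 30))
        assert partial_correlation(x, y, z).r == pytest.approx(
            partial_correlation(y, x, z).r, abs=1e-15
        )

    def test_matches_pingouin(self):
        rng = np.random.default_rng(41)
        data = pd.DataFrame(rng.normal(size=(60, 3)), columns=["x", "y", "z"])
        data["y"] += 0.5 * data["z"]
        res = partial_correlation(data["x"], data["y"], data["z"])
        ref = pg.partial_corr(data=data, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_collinear_control_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(FitError, match="collinear"):
            partial_correlation(x, np.arange(10.0)[::-1], 2 * x + 1)

    def test_type_one_error_is_calibrated(self, partial_type1_rate):
        assert 0.03 <= partial_type1_rate <= 0.07
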