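"""Shared fixtures, including the seeded Monte-Carlo calibration studies.

The expensive simulation studies (test-size calibration of the slope
contrast, null calibration of the partial correlation, parameter recovery
from the synthetic generator) are session-scoped so the unit suite and
the acceptance checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import craniomorph as cm
from craniomorph import allometry, factors, preprocess, simulate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dataset() -> cm.Dataset:
    return cm.make_paper_like_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_analysis(fixture_dataset) -> cm.AnalysisResult:
    return cm.run_analysis(
        fixture_dataset, cm.AnalysisOptions(seed=1, robust_reps=100)
    )


def _vector_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for (reps, n) arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    return (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))


@pytest.fixture(scope="session")
def clarke_type1_rate() -> float:
    """Empirical size of the slope-contrast test at alpha = 0.05.

    2000 replicate pairs of bivariate samples (n = 50 each) with the same
    true RMA slope; the rejection rate of the test at 5% is returned.
    """
    rng = np.random.default_rng(20240501)
    n, reps, rho = 50, 2000, 0.8
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    def sample():
        z = rng.standard_normal(size=(reps, n, 2)) @ chol.T
        x, y = z[..., 0], z[..., 1]
        sx = x.std(axis=1, ddof=1)
        sy = y.std(axis=1, ddof=1)
        r = _vector_pearson(x, y)
        return np.sign(r) * sy / sx, r

    b1, r1 = sample()
    b2, r2 = sample()
    _, _, p = allometry.clarke_statistic(b1, r1, n, b2, r2, n)
    return float(np.mean(p < 0.05))


@pytest.fixture(scope="session")
def partial_type1_rate() -> float:
    """Empirical size of the partial-correlation t-test at alpha = 0.05.

    x and y depend on the control z but are conditionally independent, so
    the true partial correlation is zero; 2000 seeded replicates at n = 30.
    """
    rng = np.random.default_rng(77)
    n, reps = 30, 2000
    z = rng.standard_normal((reps, n))
    x = z + rng.standard_normal((reps, n))
    y = z + rng.standard_normal((reps, n))
    r_xy = _vector_pearson(x, y)
    r_xz = _vector_pearson(x, z)
    r_yz = _vector_pearson(y, z)
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    from scipy import stats

    t = r * np.sqrt((n - 3) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 3)
    return float(np.mean(p < 0.05))


@pytest.fixture(scope="session")
def slope_recovery_study() -> dict:
    """Parameter recovery of the generating trajectory from synthetic data.

    100 replicates of a two-group dataset: an ontogenetic series (60
    adults + 60 juveniles, allometry 0.8 neurocranial / 1.2
    splanchnocranial, noise 0.01) next to a laterally transposed adult
    group that anchors the shape axis.  Per replicate the factor model is
    fitted on everything, the size factor is identified by the isometry
    diagnostic, and the series' shape scores are regressed on its size
    scores by RMA.  The true value is the population RMA slope of the
    generating model pushed through that replicate's scoring map,
    including the measurement-noise contribution to both score variances.
    """
    b = np.array([0.8, 0.8, 0.8, 1.2, 1.2, 1.2])
    noise_sd = 0.01
    slopes, covered = [], []
    for rep in range(100):
        series = simulate.GroupConfig(name="A", group="extant", n_adults=60, n_juveniles=60)
        anchor = simulate.GroupConfig(name="B", group="other", n_adults=80, shape_shift=0.08)
        config = simulate.SyntheticConfig(
            groups=(series, anchor), allometry=tuple(b), noise_sd=noise_sd, seed=1000 + rep
        )
        ds = simulate.generate(config)
        fm = factors.fit_factors(preprocess.log_transform(ds), k=2)
        iso = factors.isometry_angle(fm)
        size_col, shape_col = (
            (0, 1) if iso.angle_to_factor1 < iso.angle_to_factor2 else (1, 0)
        )
        # orient the shape factor neurocranium-positive and the size factor
        # all-positive so the slope sign is convention-independent
        shape_flip = -1.0 if fm.loadings.iloc[:3, shape_col].sum() < 0 else 1.0
        size_flip = -1.0 if fm.loadings.iloc[:, size_col].sum() < 0 else 1.0
        scores = fm.scores.to_numpy().copy()
        scores[:, shape_col] *= shape_flip
        scores[:, size_col] *= size_flip
        mask = np.array([r.taxon == "A" for r in ds.records])
        fit = allometry.fit_rma(
            scores[mask, size_col], scores[mask, shape_col], intercept_ci_method="analytic"
        )

        # population score covariance of the series under the generating
        # model: log measurements = c + s*b + noise, s a two-stage mixture
        juv_mean = series.adult_size_mean - 0.18
        var_s = (series.adult_size_sd**2 + series.juvenile_size_sd**2) / 2 + (
            (series.adult_size_mean - juv_mean) / 2
        ) ** 2
        m = fm.scoring_coefficients.to_numpy().T / fm.sds.to_numpy()  # 2 x 6 map
        cov_logs = var_s * np.outer(b, b) + noise_sd**2 * np.eye(6)
        cov_scores = m @ cov_logs @ m.T
        vx = cov_scores[size_col, size_col]
        vy = cov_scores[shape_col, shape_col]
        cxy = shape_flip * size_flip * cov_scores[size_col, shape_col]
        true_slope = np.sign(cxy) * np.sqrt(vy / vx)
        slopes.append(fit.slope)
        covered.append(fit.slope_ci[0] <= true_slope <= fit.slope_ci[1])
    return {"slopes": np.array(slopes), "coverage": float(np.mean(covered))}
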