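"""ITS Poisson fitting, counterfactual totals and delta-method SEs.

The fitter is cross-checked against an independent brute-force oracle:
an iteratively refined dense grid over the coefficient space that
maximises the Poisson log-likelihood directly, never calling the
fitting code under test.
"""

import numpy as np
import pandas as pd
import pytest

from cohortshift import (
    CounterfactualSummary,
    ExposureWindow,
    ModelSpec,
    counterfactual_path,
    counterfactual_summary,
    counterfactual_total,
    deseasonalise,
    expected_means,
    fit_all_groups,
    fit_poisson_its,
    generate_group_series,
    relative_difference,
    true_counterfactual_summary,
)
from cohortshift.series import build_design_matrix, period_range


# ---------------------------------------------------------------------------
# Brute-force likelihood-grid oracle
# ---------------------------------------------------------------------------

def poisson_loglik(y, X, beta):
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta)))


def grid_mle(y, X, centre, half_width=4.0, points=13, stages=14):
    """Zooming dense-grid maximiser of the Poisson log-likelihood.

    Evaluates the likelihood on a full cartesian grid around `centre`,
    re-centres on the best point and shrinks; concavity of the Poisson
    log-likelihood guarantees convergence to the global optimum.
    Resolution after the final stage is ~1e-5 per coordinate.
    """
    beta = np.asarray(centre, dtype=float)
    width = half_width
    k = len(beta)
    for _ in range(stages):
        axes = [beta[j] + np.linspace(-width, width, points) for j in range(k)]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)
        ll = np.sum(y * (cand @ X.T) - np.exp(cand @ X.T), axis=1)
        beta = cand[np.argmax(ll)]
        width *= 0.35
    return beta


@pytest.mark.parametrize("n_cols", [1, 2, 3])
def test_fit_matches_bruteforce_grid_oracle(n_cols):
    """MLE equals the independent grid maximiser on random small series."""
    rng = np.random.default_rng(2024)
    for _ in range(7):
        n = int(rng.integers(8, 21))
        cols = {"intercept": np.ones(n)}
        if n_cols >= 2:
            cols["t"] = np.linspace(-0.5, 0.5, n)
        if n_cols >= 3:
            cols["ind"] = (np.arange(n) >= n - 3).astype(float)
        X = pd.DataFrame(cols)
        beta_true = rng.uniform(-1, 1, size=n_cols)
        beta_true[0] += 2.5  # keep counts away from all-zero
        y = rng.poisson(np.exp(X.to_numpy() @ beta_true))
        if y.sum() == 0:
            continue
        fit = fit_poisson_its(y, X)
        centre = np.zeros(n_cols)
        centre[0] = np.log(max(y.mean(), 0.5))
        oracle = grid_mle(y.astype(float), X.to_numpy(), centre)
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-4)


def test_intercept_only_constant_counts():
    """Poisson MLE of a constant mean is the sample mean."""
    X = pd.DataFrame({"intercept": np.ones(10)})
    fit = fit_poisson_its(np.full(10, 8), X)
    assert fit.params["intercept"] == pytest.approx(np.log(8.0), abs=1e-8)
    assert np.allclose(fit.fitted_means, 8.0)
    assert fit.converged


def test_fit_preconditions():
    X = pd.DataFrame({"intercept": np.ones(6), "zero": np.zeros(6)})
    with pytest.raises(ValueError, match="rank deficient"):
        fit_poisson_its(np.arange(6), X)
    with pytest.raises(ValueError, match="all counts are zero"):
        fit_poisson_its(np.zeros(6), X[["intercept"]])
    with pytest.raises(ValueError, match="nonnegative integers"):
        fit_poisson_its(np.array([1.0, -2.0, 3.0, 1, 1, 1]), X[["intercept"]])


def test_score_identity_and_total_match(two_group_scenario):
    """Canonical link: sum (y - mu) x = 0 and fitted total = observed total."""
    series = generate_group_series(two_group_scenario)
    X = build_design_matrix(series, two_group_scenario.model_spec())
    for g in series.groups:
        y = series.counts[g].to_numpy()
        fit = fit_poisson_its(y, X)
        score = X.to_numpy().T @ (y - fit.fitted_means.to_numpy())
        assert np.max(np.abs(score)) < 1e-6
        assert abs(fit.fitted_means.sum() - y.sum()) < 1e-6
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)


# ---------------------------------------------------------------------------
# Deseasonalised and counterfactual trajectories
# ---------------------------------------------------------------------------

def _fitted_scenario(scenario):
    series = generate_group_series(scenario)
    fits, summaries, design = fit_all_groups(series, scenario.model_spec())
    return series, fits, summaries, design


def test_deseasonalise_identity_without_seasonal_columns():
    periods = period_range("2020-01", "2021-12", "monthly")
    exposure = ExposureWindow("2020-12", "2021-12")
    X = pd.DataFrame({
        "intercept": np.ones(24),
        "exposure": np.array([p in set(exposure.periods("monthly"))
                              for p in periods], dtype=float),
    }, index=periods)
    rng = np.random.default_rng(3)
    fit = fit_poisson_its(rng.poisson(50, size=24), X)
    pd.testing.assert_series_equal(deseasonalise(fit, X), fit.fitted_means)


def test_deseasonalised_curve_tracks_true_trend(two_group_scenario):
    """With known truth, the deseasonalised path follows exp(trend+exposure)."""
    series, fits, _, design = _fitted_scenario(two_group_scenario)
    truth = expected_means(two_group_scenario, with_season=False)
    for g in series.groups:
        des = deseasonalise(fits[g], design)
        rel_err = np.abs(des.to_numpy() / truth[g].to_numpy() - 1.0)
        assert np.median(rel_err) < 0.05


def test_counterfactual_path_drops_only_the_exposure_term(two_group_scenario):
    series, fits, _, design = _fitted_scenario(two_group_scenario)
    fit = fits["A"]
    cf = counterfactual_path(fit, design)
    des = deseasonalise(fit, design).loc[cf.index]
    ratio = des / cf
    # fitted path exceeds counterfactual by exp(exposure coef) at every period
    assert np.allclose(ratio, np.exp(fit.params["exposure"]))
    # group B has no true effect; its estimated effect is small, so paths align
    cf_b = counterfactual_path(fits["B"], design)
    des_b = deseasonalise(fits["B"], design).loc[cf_b.index]
    assert np.allclose(des_b / cf_b, np.exp(fits["B"].params["exposure"]))


def test_zero_exposure_coefficient_makes_counterfactual_equal_fitted(
        two_group_scenario):
    """Forcing the exposure coefficient to 0 collapses the counterfactual."""
    series, fits, _, design = _fitted_scenario(two_group_scenario)
    fit = fits["A"]
    fit.params["exposure"] = 0.0
    exposed = design["exposure"] == 1.0
    cf = counterfactual_path(fit, design)
    des = deseasonalise(fit, design).loc[exposed]
    pd.testing.assert_series_equal(cf, des)
    total, _ = counterfactual_total(fit, design)
    refit_means = np.exp(design.to_numpy() @ fit.params.to_numpy())
    assert total == pytest.approx(refit_means[exposed.to_numpy()].sum(), rel=1e-12)


def test_counterfactual_path_near_truth(two_group_scenario):
    series, fits, _, design = _fitted_scenario(two_group_scenario)
    truth = expected_means(two_group_scenario, with_exposure=False,
                           with_season=False)
    cf = counterfactual_path(fits["A"], design)
    rel_err = np.abs(cf.to_numpy() / truth["A"].loc[cf.index].to_numpy() - 1.0)
    assert np.median(rel_err) < 0.05


# ---------------------------------------------------------------------------
# Counterfactual totals and the delta-method SE
# ---------------------------------------------------------------------------

def test_counterfactual_total_se_matches_parametric_simulation(
        two_group_scenario):
    """Delta-method SE vs drawing beta ~ N(betahat, Cov) and recomputing."""
    series, fits, _, design = _fitted_scenario(two_group_scenario)
    fit = fits["A"]
    total, se = counterfactual_total(fit, design)
    exposed = design["exposure"].to_numpy() == 1.0
    Xcf = design.copy()
    Xcf["exposure"] = 0.0
    Xcf = Xcf.to_numpy()[exposed]
    rng = np.random.default_rng(99)
    betas = rng.multivariate_normal(fit.params.to_numpy(), fit.cov.to_numpy(),
                                    size=100_000, method="cholesky")
    sim_totals = np.exp(betas @ Xcf.T).sum(axis=1)
    assert se == pytest.approx(sim_totals.std(), rel=0.05)
    assert total == pytest.approx(sim_totals.mean(), rel=0.01)


def test_counterfactual_total_recovers_truth(two_group_scenario):
    _, _, summaries, _ = _fitted_scenario(two_group_scenario)
    truth = true_counterfactual_summary(two_group_scenario)
    for s in summaries:
        t = truth.loc[s.group, "counterfactual_total"]
        assert abs(s.counterfactual_total - t) < 4 * s.counterfactual_se + 3 * np.sqrt(t)


# ---------------------------------------------------------------------------
# Relative differences
# ---------------------------------------------------------------------------

def test_relative_difference_arithmetic_and_collapse():
    s = CounterfactualSummary("A", observed_total=107.0,
                              counterfactual_total=100.0, counterfactual_se=0.0)
    pct, (lo, hi) = relative_difference(s, np.full(1000, 100.0))
    assert pct == pytest.approx(7.0)
    assert lo == pytest.approx(7.0)
    assert hi == pytest.approx(7.0)


def test_relative_difference_ci_widens_with_se():
    s = CounterfactualSummary("A", 107.0, 100.0, 0.0)
    rng = np.random.default_rng(1)
    z = rng.standard_normal(20_000)
    widths, intervals = [], []
    for se in (1.0, 2.0, 4.0):
        pct, (lo, hi) = relative_difference(s, 100.0 + se * z)
        assert lo <= pct <= hi
        intervals.append((lo, hi))
        widths.append(hi - lo)
    assert widths[0] < widths[1] < widths[2]
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        assert lo2 <= lo1 and hi1 <= hi2  # nested intervals


def test_relative_difference_rejects_nonpositive_draws():
    s = CounterfactualSummary("A", 107.0, 100.0, 60.0)
    with pytest.raises(ValueError, match="nonpositive"):
        relative_difference(s, np.array([100.0, -5.0]))
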