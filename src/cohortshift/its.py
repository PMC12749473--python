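"""Interrupted-time-series Poisson regression and counterfactual totals.

One model per socioeconomic group and country: live-birth counts are
regressed, with a log link and no offset, on an intercept, linear and
quadratic terms in the scaled period index, week/month-of-year fixed
effects (first period of the year as reference), optional shock
indicators, and a single exposure-period indicator whose coefficient is
the average pandemic effect over the whole exposed window.

The counterfactual number of births over the exposed window ("had
pre-pandemic trends continued") is the sum of fitted means with the
exposure indicator set to zero.  Its standard error comes from the
delta method on the coefficient covariance.  Two conventions apply:

* counterfactual *totals* retain seasonal and shock contributions —
  they are real births in those calendar periods;
* plotted deseasonalised and counterfactual *paths* strip seasonal and
  shock contributions, mirroring the usual trend-figure convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .series import GroupedCountSeries, ModelSpec

CONVERGENCE_TOL = 1e-10
MAX_ITERATIONS = 100


@dataclass
class PoissonFit:
    """Result of one group's ITS Poisson regression."""

    params: pd.Series             # coefficients keyed by design-column name
    cov: pd.DataFrame             # covariance of the coefficients
    fitted_means: pd.Series       # exp(X beta) per period
    log_likelihood: float
    converged: bool
    n_iterations: int

    def require_converged(self) -> "PoissonFit":
        if not self.converged:
            raise RuntimeError("Poisson ITS fit did not converge; refusing to use it")
        return self


@dataclass(frozen=True)
class CounterfactualSummary:
    """Observed and counterfactual births over the exposed window, one group."""

    group: str
    observed_total: float
    counterfactual_total: float
    counterfactual_se: float

    def __post_init__(self):
        if not np.isfinite(self.counterfactual_total):
            raise ValueError(f"group {self.group!r}: non-finite counterfactual total")
        if not np.isfinite(self.counterfactual_se) or self.counterfactual_se < 0:
            raise ValueError(f"group {self.group!r}: invalid counterfactual SE")


def fit_poisson_its(counts: pd.Series | np.ndarray, design: pd.DataFrame) -> PoissonFit:
    """Maximum-likelihood Poisson fit of one group's count series.

    Log link, no offset; IRLS with relative-log-likelihood tolerance
    1e-10, at most 100 iterations.  The covariance is the inverse
    Fisher information at the optimum.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ValueError("counts and design matrix have mismatched lengths")
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if y.sum() == 0:
        raise ValueError("all counts are zero; the model is not identifiable")
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=MAX_ITERATIONS, tol=CONVERGENCE_TOL, scale=1.0)
    n_iter = len(res.fit_history["deviance"]) - 1
    converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.params))
    params = pd.Series(res.params, index=design.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params()),
                       index=design.columns, columns=design.columns)
    fitted = pd.Series(np.exp(X @ params.to_numpy()), index=design.index)
    return PoissonFit(params=params, cov=cov, fitted_means=fitted,
                      log_likelihood=float(res.llf), converged=converged,
                      n_iterations=n_iter)


def _zeroed(design: pd.DataFrame, *, season: bool = False, shocks: bool = False,
            exposure: bool = False) -> pd.DataFrame:
    X = design.copy()
    for col in X.columns:
        if season and col.startswith("season_"):
            X[col] = 0.0
        if shocks and col.startswith("shock_"):
            X[col] = 0.0
        if exposure and col == "exposure":
            X[col] = 0.0
    return X


def deseasonalise(fit: PoissonFit, design: pd.DataFrame) -> pd.Series:
    """Fitted trajectory at the reference seasonal level, shocks removed.

    Keeps the exposure contribution: this is the solid trend line, not
    the counterfactual.
    """
    fit.require_converged()
    X = _zeroed(design, season=True, shocks=True)
    return pd.Series(np.exp(X.to_numpy() @ fit.params.to_numpy()), index=design.index)


def counterfactual_path(fit: PoissonFit, design: pd.DataFrame) -> pd.Series:
    """Deseasonalised path with the exposure effect also removed.

    Restricted to the exposed periods: the dashed "had the pandemic
    never happened" line.
    """
    fit.require_converged()
    exposed = design["exposure"].to_numpy() == 1.0
    if not exposed.any():
        raise ValueError("exposure window is empty in the design matrix")
    X = _zeroed(design, season=True, shocks=True, exposure=True).loc[exposed]
    return pd.Series(np.exp(X.to_numpy() @ fit.params.to_numpy()), index=X.index)


def counterfactual_total(fit: PoissonFit, design: pd.DataFrame) -> tuple[float, float]:
    """Counterfactual total births over the exposed window, with SE.

    total = sum over exposed periods of exp(x_t' beta) with the
    exposure column zeroed and seasonal/shock columns retained (the
    total lives on the observed count scale).  Delta method:
    g = sum mu_t x_t,  se = sqrt(g' Cov g).
    """
    fit.require_converged()
    exposed = design["exposure"].to_numpy() == 1.0
    if not exposed.any():
        raise ValueError("exposure window is empty in the design matrix")
    X = _zeroed(design, exposure=True).loc[exposed].to_numpy()
    mu = np.exp(X @ fit.params.to_numpy())
    total = float(mu.sum())
    g = X.T @ mu
    var = float(g @ fit.cov.to_numpy() @ g)
    if not np.isfinite(var) or var < -1e-8 * total**2:
        raise ValueError("non-finite or negative delta-method variance "
                         "(singular covariance?)")
    return total, float(np.sqrt(max(var, 0.0)))


def counterfactual_summary(group: str, counts: pd.Series, fit: PoissonFit,
                           design: pd.DataFrame) -> CounterfactualSummary:
    """Bundle observed and counterfactual totals for one group."""
    exposed = design["exposure"].to_numpy() == 1.0
    observed = float(np.asarray(counts, dtype=float)[exposed].sum())
    total, se = counterfactual_total(fit, design)
    return CounterfactualSummary(group=group, observed_total=observed,
                                 counterfactual_total=total, counterfactual_se=se)


def relative_difference(summary: CounterfactualSummary,
                        draws: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Relative change in births vs the counterfactual, with percentile CI.

    percent = 100 (observed - counterfactual) / counterfactual; the CI
    reuses the same normal draws of the counterfactual total as the
    composition CI: bounds are the 2.5th/97.5th percentiles of
    100 (observed/draw - 1).
    """
    draws = np.asarray(draws, dtype=float)
    if np.any(draws <= 0):
        raise ValueError(
            f"group {summary.group!r}: nonpositive counterfactual draw; "
            "rerun with truncate_at_zero for tiny-count scenarios")
    percent = 100.0 * (summary.observed_total - summary.counterfactual_total) \
        / summary.counterfactual_total
    rel = 100.0 * (summary.observed_total / draws - 1.0)
    lo, hi = np.percentile(rel, [2.5, 97.5])
    return percent, (float(lo), float(hi))


def fit_all_groups(series: GroupedCountSeries, spec: ModelSpec,
                   design: pd.DataFrame | None = None
                   ) -> tuple[dict[str, PoissonFit], list[CounterfactualSummary],
                              pd.DataFrame]:
    """Fit every group of a series and collect counterfactual summaries.

    Returns the per-group fits, the summaries (in series group order),
    and the shared design matrix.
    """
    from .series import build_design_matrix
    if design is None:
        design = build_design_matrix(series, spec)
    fits: dict[str, PoissonFit] = {}
    summaries: list[CounterfactualSummary] = []
    for group in series.groups:
        y = series.counts[group]
        fit = fit_poisson_its(y, design)
        fits[group] = fit
        summaries.append(counterfactual_summary(group, y, fit, design))
    return fits, summaries, design
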