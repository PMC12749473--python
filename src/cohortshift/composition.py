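"""Cohort-composition differences and Monte-Carlo percentile CIs.

Given per-group observed and counterfactual birth totals over the
exposed window, the observed composition is p_g = observed_g / sum
observed, the counterfactual composition q_g = counterfactual_g / sum
counterfactual, and the headline quantity is the percentage-point
difference delta_g = 100 (p_g - q_g).

Uncertainty follows a three-step parametric Monte-Carlo scheme:

1. draw each group's counterfactual total independently from
   Normal(point estimate, standard error);
2. renormalise the draws into a counterfactual composition;
3. difference against the observed composition in percentage points.

Repeating 10,000 times, the 95% CI bounds are the 2.5th and 97.5th
percentiles of each group's distribution of differences.  Draws are
untruncated by default (each replicate only needs a positive sum);
``truncate_at_zero`` clamps draws at 0 for tiny-count scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .its import CounterfactualSummary
from .synthetic import SyntheticScenario, generate_group_series, true_counterfactual_summary


@dataclass
class CompositionResult:
    """Observed vs counterfactual cohort composition with MC intervals.

    ``table`` has one row per group: observed_prop, counterfactual_prop,
    delta_pp, ci_lo_pp, ci_hi_pp.  ``draws`` holds the raw normal draws
    of the counterfactual totals (n_draws x groups) so relative-change
    CIs can reuse the same randomness.
    """

    table: pd.DataFrame
    n_draws: int
    seed: int | None
    draws: pd.DataFrame


def _validate_summaries(summaries: list[CounterfactualSummary]) -> None:
    if len(summaries) < 2:
        raise ValueError("composition needs at least 2 groups")
    labels = [s.group for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    for s in summaries:
        if s.counterfactual_total <= 0:
            raise ValueError(f"group {s.group!r}: counterfactual total must be > 0")
    if all(s.observed_total == 0 for s in summaries):
        raise ValueError("all observed totals are zero")


def composition_delta(summaries: list[CounterfactualSummary]) -> pd.DataFrame:
    """Point compositions and percentage-point deltas per group."""
    _validate_summaries(summaries)
    obs = np.array([s.observed_total for s in summaries], dtype=float)
    cf = np.array([s.counterfactual_total for s in summaries], dtype=float)
    p = obs / obs.sum()
    q = cf / cf.sum()
    return pd.DataFrame({
        "observed_prop": p,
        "counterfactual_prop": q,
        "delta_pp": 100.0 * (p - q),
    }, index=pd.Index([s.group for s in summaries], name="group"))


def mc_composition_ci(summaries: list[CounterfactualSummary],
                      n_draws: int = 10_000, seed: int | None = None,
                      truncate_at_zero: bool = False) -> CompositionResult:
    """Three-step Monte-Carlo percentile CIs for the composition deltas.

    One random stream per analysis; within each replicate the group
    draws are filled in the given group order, so results are
    reproducible bit-for-bit given seed and group order.  Percentiles
    use linear interpolation between order statistics.
    """
    _validate_summaries(summaries)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_draws < 1000:
        warnings.warn(f"n_draws={n_draws} is low for stable 95% CI bounds",
                      UserWarning, stacklevel=2)
    point = composition_delta(summaries)
    cf = np.array([s.counterfactual_total for s in summaries], dtype=float)
    se = np.array([s.counterfactual_se for s in summaries], dtype=float)
    p = point["observed_prop"].to_numpy()

    rng = np.random.default_rng(seed)
    # row-major standard normals: each replicate's groups drawn in order
    draws = cf + se * rng.standard_normal((n_draws, len(summaries)))
    if truncate_at_zero:
        n_clamped = int((draws < 0).sum())
        if n_clamped:
            warnings.warn(f"clamped {n_clamped} negative counterfactual draws at 0",
                          UserWarning, stacklevel=2)
        draws = np.maximum(draws, 0.0)
    totals = draws.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("a Monte-Carlo replicate has nonpositive total "
                         "counterfactual births; cannot renormalise")
    q_draws = draws / totals[:, None]
    d_draws = 100.0 * (p[None, :] - q_draws)
    lo, hi = np.percentile(d_draws, [2.5, 97.5], axis=0)

    table = point.copy()
    table["ci_lo_pp"] = lo
    table["ci_hi_pp"] = hi
    groups = [s.group for s in summaries]
    return CompositionResult(
        table=table, n_draws=n_draws, seed=seed,
        draws=pd.DataFrame(draws, columns=groups))


def coverage_experiment(scenario: SyntheticScenario, n_replicates: int,
                        n_draws: int, seed: int | None = None) -> pd.DataFrame:
    """Empirical coverage of the 95% MC interval against the known truth.

    Repeatedly simulates a register from the scenario, runs the full
    fit-and-compose analysis, and records whether each group's CI
    contains the true percentage-point delta implied by the generative
    parameters.  Returns per-group coverage with its binomial
    Monte-Carlo standard error.
    """
    from .its import fit_all_groups
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_replicates < 50:
        warnings.warn(f"n_replicates={n_replicates} gives a noisy coverage estimate",
                      UserWarning, stacklevel=2)
    truth = true_counterfactual_summary(scenario)["delta_pp"]
    spec = scenario.model_spec()
    rng = np.random.default_rng(seed)
    groups = list(scenario.groups)
    hits = pd.Series(0, index=pd.Index(groups, name="group"), dtype=int)
    design = None
    for _ in range(n_replicates):
        series = generate_group_series(scenario, rng=rng)
        _, summaries, design = fit_all_groups(series, spec, design=design)
        mc_seed = int(rng.integers(0, 2**31 - 1))
        result = mc_composition_ci(summaries, n_draws=n_draws, seed=mc_seed)
        tab = result.table
        covered = (tab["ci_lo_pp"] <= truth.loc[tab.index]) & \
                  (truth.loc[tab.index] <= tab["ci_hi_pp"])
        hits += covered.astype(int)
    coverage = hits / n_replicates
    mc_se = np.sqrt(coverage * (1 - coverage) / n_replicates)
    return pd.DataFrame({"coverage": coverage, "mc_se": mc_se,
                         "true_delta_pp": truth, "n_replicates": n_replicates})
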