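"""End-to-end orchestration: simulate/load -> build -> fit -> compose.

Reads a single YAML configuration describing one analysis (one
"country"), runs every stage, and writes tidy CSVs, diagnostic figures
and a run manifest into the output directory.  Given the same config
(including the seed) the tabular outputs are byte-identical across
reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import CompositionResult, mc_composition_ci
from .its import PoissonFit, counterfactual_path, deseasonalise, fit_all_groups, \
    relative_difference
from .series import (
    ExposureWindow,
    GroupedCountSeries,
    ModelSpec,
    ShockWindow,
    aggregate_records,
    assign_quintiles,
    check_frequency,
    filter_records,
)
from .synthetic import SyntheticScenario, generate_group_series

logger = logging.getLogger("cohortshift")

#: Conventions baked into this implementation, recorded in every manifest.
DESIGN_FLAGS = {
    "counterfactual_totals_retain_seasonality": True,
    "week53_seasonal_merged_with_week52": True,
    "quintile_ties_go_to_lower_quintile": True,
    "time_index_centred_and_scaled_by_n": True,
    "mc_draws_untruncated_by_default": True,
}


@dataclass
class AnalysisConfig:
    """Everything needed to run one analysis, parsed from YAML."""

    frequency: str
    outdir: str
    seed: int
    n_draws: int = 10_000
    # exactly one input source:
    scenario_file: str | None = None
    records_csv: str | None = None
    counts_csv: str | None = None
    # record handling
    group_column: str | None = None
    quintile_score_column: str | None = None
    filters: dict = field(default_factory=dict)
    # model
    exposure: ExposureWindow | None = None
    shocks: tuple[ShockWindow, ...] = ()
    truncate_at_zero: bool = False

    def __post_init__(self):
        check_frequency(self.frequency)
        sources = [s for s in (self.scenario_file, self.records_csv, self.counts_csv)
                   if s is not None]
        if len(sources) != 1:
            raise ValueError("config must name exactly one input source "
                             "(scenario_file | records_csv | counts_csv)")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required (stochastic stages run)")
        if self.exposure is None:
            self.exposure = ExposureWindow.default(self.frequency)
        self.shocks = tuple(sw if isinstance(sw, ShockWindow) else ShockWindow(**sw)
                            for sw in self.shocks)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if d.get("exposure"):
            d["exposure"] = ExposureWindow(**d["exposure"])
        if d.get("shocks"):
            d["shocks"] = tuple(ShockWindow(**s) for s in d["shocks"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        return d


def proportion_series(series: GroupedCountSeries) -> pd.DataFrame:
    """Observed per-period share of each group in the birth cohort."""
    totals = series.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"period {zero.index[0]} has zero total births; "
                         "proportions undefined")
    return series.counts.div(totals, axis=0)


def _load_series(config: AnalysisConfig) -> GroupedCountSeries:
    if config.scenario_file:
        scenario = SyntheticScenario.from_yaml(config.scenario_file)
        logger.info("simulate: scenario with %d groups, %s, seed=%d",
                    len(scenario.groups), scenario.frequency, scenario.seed)
        return generate_group_series(scenario)
    if config.counts_csv:
        return GroupedCountSeries.read_csv(config.counts_csv, config.frequency,
                                           exposure=config.exposure)
    records = pd.read_csv(config.records_csv)
    n0 = len(records)
    records = filter_records(records, config.filters)
    logger.info("build: %d records read, %d kept after filters", n0, len(records))
    if config.quintile_score_column:
        col = config.quintile_score_column
        if col not in records.columns:
            raise ValueError(f"quintile score column {col!r} absent from records")
        # pre-exposure births define the reference distribution
        from .series import period_of_date
        import datetime as _dt
        dates = pd.to_datetime(records["date_of_birth"]).dt.date
        exp_periods = set(config.exposure.periods(config.frequency))
        pre = records.loc[[period_of_date(d, config.frequency) not in exp_periods
                           for d in dates], col]
        group_rule = lambda df: assign_quintiles(df[col], pre)
    else:
        group_rule = config.group_column or "group"
    return aggregate_records(records, config.frequency, group_rule,
                             exposure=config.exposure)


def _paths_table(series: GroupedCountSeries, fits: dict[str, PoissonFit],
                 design: pd.DataFrame) -> pd.DataFrame:
    """Tidy period,group,series,value table of all trajectories."""
    rows = []
    for group, fit in fits.items():
        obs = series.counts[group]
        des = deseasonalise(fit, design)
        cf = counterfactual_path(fit, design)
        for name, s in (("observed", obs), ("fitted", fit.fitted_means),
                        ("deseasonalised", des), ("counterfactual", cf)):
            rows.append(pd.DataFrame({"period": s.index, "group": group,
                                      "series": name, "value": s.to_numpy()}))
    return pd.concat(rows, ignore_index=True)


def _fit_table(fits: dict[str, PoissonFit]) -> pd.DataFrame:
    rows = []
    for group, fit in fits.items():
        se = np.sqrt(np.diag(fit.cov.to_numpy()))
        rows.append(pd.DataFrame({"group": group, "term": fit.params.index,
                                  "estimate": fit.params.to_numpy(), "se": se}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _fig_group_trajectories(series, fits, design, outdir: Path) -> list[str]:
    exposure_start = np.flatnonzero(series.exposure_flag)
    x = series.t
    files = []
    for group, fit in fits.items():
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.plot(x, series.counts[group], ".", color="tab:blue", ms=3, label="observed")
        ax.plot(x, fit.fitted_means, color="grey", lw=1, label="fitted")
        ax.plot(x, deseasonalise(fit, design), color="black", lw=1.5,
                label="deseasonalised")
        cf = counterfactual_path(fit, design)
        cf_x = [series.periods.index(p) for p in cf.index]
        ax.plot(cf_x, cf, "--", color="black", lw=1.5, label="counterfactual")
        if len(exposure_start):
            ax.axvline(exposure_start[0], color="black", lw=0.8)
        ax.set_xlabel("period index")
        ax.set_ylabel("live births")
        ax.set_title(group)
        ax.legend(fontsize=8)
        f = outdir / f"trajectory_{group}.png"
        fig.savefig(f, dpi=120)
        plt.close(fig)
        files.append(f.name)
    return files


def _fig_proportions(series, outdir: Path) -> str:
    props = proportion_series(series)
    fig, ax = plt.subplots(figsize=(8, 4))
    for group in props.columns:
        ax.plot(series.t, props[group], lw=1, label=group)
    start = np.flatnonzero(series.exposure_flag)
    if len(start):
        ax.axvline(start[0], color="black", lw=0.8)
    ax.set_xlabel("period index")
    ax.set_ylabel("share of live births")
    ax.legend(fontsize=8)
    f = outdir / "proportions.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    return f.name


def _fig_deltas(result: CompositionResult, outdir: Path) -> str:
    tab = result.table
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(tab) + 1.5))
    ypos = np.arange(len(tab))[::-1]
    ax.hlines(ypos, tab["ci_lo_pp"], tab["ci_hi_pp"], color="black", lw=1.2)
    ax.plot(tab["delta_pp"], ypos, "o", color="black")
    ax.axvline(0, color="grey", lw=0.8, ls=":")
    ax.set_yticks(ypos, tab.index)
    ax.set_xlabel("observed - counterfactual share (percentage points)")
    fig.tight_layout()
    f = outdir / "composition_deltas.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    return f.name


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and write all outputs; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = ModelSpec(exposure=config.exposure, shocks=config.shocks)

    stage = "build"
    try:
        series = _load_series(config)
        series.to_csv(outdir / "counts.csv")

        stage = "fit"
        fits, summaries, design = fit_all_groups(series, spec)
        for group, fit in fits.items():
            logger.info("fit: group=%s periods=%d converged=%s iters=%d",
                        group, len(series.periods), fit.converged, fit.n_iterations)
            fit.require_converged()
        _fit_table(fits).to_csv(outdir / "fits.csv", index=False)
        _paths_table(series, fits, design).to_csv(outdir / "paths.csv", index=False)
        pd.DataFrame([{"group": s.group, "observed_total": s.observed_total,
                       "counterfactual_total": s.counterfactual_total,
                       "counterfactual_se": s.counterfactual_se}
                      for s in summaries]).to_csv(outdir / "totals.csv", index=False)

        stage = "compose"
        result = mc_composition_ci(summaries, n_draws=config.n_draws,
                                   seed=config.seed,
                                   truncate_at_zero=config.truncate_at_zero)
        comp = result.table.reset_index()
        comp["n_draws"] = result.n_draws
        comp["seed"] = result.seed
        comp.to_csv(outdir / "composition.csv", index=False)

        rel_rows = []
        for s in summaries:
            pct, (lo, hi) = relative_difference(s, result.draws[s.group].to_numpy())
            rel_rows.append({"group": s.group, "rel_diff_pct": pct,
                             "ci_lo_pct": lo, "ci_hi_pct": hi})
        pd.DataFrame(rel_rows).to_csv(outdir / "relative.csv", index=False)

        stage = "figures"
        figures = _fig_group_trajectories(series, fits, design, outdir)
        figures.append(_fig_proportions(series, outdir))
        figures.append(_fig_deltas(result, outdir))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    config_yaml = yaml.safe_dump(config.canonical_dict(), sort_keys=True)
    manifest = {
        "package": "cohortshift",
        "version": __version__,
        "config": config.canonical_dict(),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "design_flags": dict(DESIGN_FLAGS,
                             mc_draws_truncated=config.truncate_at_zero),
        "outputs": ["counts.csv", "fits.csv", "paths.csv", "totals.csv",
                    "composition.csv", "relative.csv"] + figures,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
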