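"""Calendar binning, socioeconomic grouping and design matrices.

Turns individual-level birth records (or raw count tables) into
analysis-ready grouped time series: one row per calendar period, one
column per socioeconomic group, zero-filled, with an exposure-window
flag and the covariates of the interrupted-time-series model.

Conventions
-----------
* Weekly series use the ISO-8601 week calendar (Monday start); periods
  are labelled ``YYYY-Www``.  Monthly series use calendar months,
  labelled ``YYYY-MM``.
* The default exposure window is the pandemic-conception birth cohort:
  13 months starting December 2020 for monthly series, 54 weeks
  starting the 51st ISO week of 2020 for weekly series.
* The sequential time index is centred and scaled,
  ``t_lin = (t - mean(t)) / n_periods``, before the quadratic term is
  formed, for numerical conditioning.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cohortshift")

WEEKLY = "weekly"
MONTHLY = "monthly"

MISSING_LABEL = "missing"

#: Default exposure windows for the cohort conceived after pandemic onset
#: (births December 2020 - December 2021): 13 monthly or 54 weekly periods.
DEFAULT_EXPOSURE = {
    MONTHLY: ("2020-12", "2021-12"),
    WEEKLY: ("2020-W51", "2021-W51"),
}

_WEEK_RE = re.compile(r"^(\d{4})-W(\d{2})$")
_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


# ---------------------------------------------------------------------------
# Period arithmetic
# ---------------------------------------------------------------------------

def check_frequency(frequency: str) -> str:
    if frequency not in (WEEKLY, MONTHLY):
        raise ValueError(f"frequency must be '{WEEKLY}' or '{MONTHLY}', got {frequency!r}")
    return frequency


def iso_weeks_in_year(year: int) -> int:
    """Number of ISO weeks (52 or 53) in a given ISO year."""
    return _dt.date(year, 12, 28).isocalendar().week


def parse_period(label: str, frequency: str) -> tuple[int, int]:
    """Parse ``YYYY-Www`` / ``YYYY-MM`` into (year, week-or-month)."""
    check_frequency(frequency)
    m = (_WEEK_RE if frequency == WEEKLY else _MONTH_RE).match(label)
    if not m:
        raise ValueError(f"cannot parse {frequency} period label {label!r}")
    year, sub = int(m.group(1)), int(m.group(2))
    limit = iso_weeks_in_year(year) if frequency == WEEKLY else 12
    if not 1 <= sub <= limit:
        raise ValueError(f"period {label!r} out of range (max {limit})")
    return year, sub


def format_period(year: int, sub: int, frequency: str) -> str:
    return f"{year}-W{sub:02d}" if frequency == WEEKLY else f"{year}-{sub:02d}"


def period_of_date(date: _dt.date, frequency: str) -> str:
    """Calendar period containing a date (ISO week or calendar month)."""
    check_frequency(frequency)
    if frequency == WEEKLY:
        iso = date.isocalendar()
        return format_period(iso.year, iso.week, WEEKLY)
    return format_period(date.year, date.month, MONTHLY)


def period_start_date(label: str, frequency: str) -> _dt.date:
    year, sub = parse_period(label, frequency)
    if frequency == WEEKLY:
        return _dt.date.fromisocalendar(year, sub, 1)
    return _dt.date(year, sub, 1)


def period_dates(label: str, frequency: str) -> list[_dt.date]:
    """All calendar days belonging to a period."""
    start = period_start_date(label, frequency)
    if frequency == WEEKLY:
        return [start + _dt.timedelta(days=i) for i in range(7)]
    year, month = parse_period(label, MONTHLY)
    nxt = _dt.date(year + (month == 12), month % 12 + 1, 1)
    return [start + _dt.timedelta(days=i) for i in range((nxt - start).days)]


def next_period(label: str, frequency: str) -> str:
    year, sub = parse_period(label, frequency)
    limit = iso_weeks_in_year(year) if frequency == WEEKLY else 12
    if sub < limit:
        return format_period(year, sub + 1, frequency)
    return format_period(year + 1, 1, frequency)


def period_range(start: str, end: str, frequency: str) -> list[str]:
    """Inclusive, gap-free run of period labels from start to end."""
    if parse_period(start, frequency) > parse_period(end, frequency):
        raise ValueError(f"start period {start!r} after end period {end!r}")
    out = [start]
    while out[-1] != end:
        out.append(next_period(out[-1], frequency))
        if len(out) > 100_000:  # defensive: malformed end label
            raise ValueError(f"period range {start}..{end} did not terminate")
    return out


def period_of_year(label: str, frequency: str) -> int:
    """Week-of-year (1..53) or month-of-year (1..12)."""
    return parse_period(label, frequency)[1]


def seasonal_level(label: str, frequency: str) -> int:
    """Seasonal stratum of a period; ISO week 53 is merged into week 52."""
    poy = period_of_year(label, frequency)
    if frequency == WEEKLY and poy == 53:
        return 52
    return poy


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureWindow:
    """Calendar window of births exposed to potential compositional change."""

    start: str
    end: str

    def periods(self, frequency: str) -> list[str]:
        return period_range(self.start, self.end, frequency)

    @classmethod
    def default(cls, frequency: str) -> "ExposureWindow":
        start, end = DEFAULT_EXPOSURE[check_frequency(frequency)]
        return cls(start, end)


@dataclass(frozen=True)
class ShockWindow:
    """Level-shift window absorbing a known transient disturbance.

    E.g. the Zika-epidemic dip (August-December 2016) or a change in
    data collection spanning whole years.
    """

    label: str
    start: str
    end: str

    def periods(self, frequency: str) -> list[str]:
        return period_range(self.start, self.end, frequency)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one group's ITS regression."""

    exposure: ExposureWindow
    shocks: tuple[ShockWindow, ...] = ()
    trend_degree: int = 2
    seasonal_reference: int = 1  # January / first ISO week

    def __post_init__(self):
        if self.trend_degree != 2:
            raise ValueError("only quadratic secular trends are supported")


@dataclass
class GroupedCountSeries:
    """Per-period, per-group live-birth counts with calendar metadata.

    ``counts`` is indexed by period label (strictly increasing, gap
    free) with one integer column per group, zero-filled.
    """

    frequency: str
    counts: pd.DataFrame
    exposure: ExposureWindow | None = None

    def __post_init__(self):
        check_frequency(self.frequency)
        periods = list(self.counts.index)
        if not periods:
            raise ValueError("empty series")
        expected = period_range(periods[0], periods[-1], self.frequency)
        if periods != expected:
            raise ValueError("periods must be strictly increasing with no gaps or duplicates")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        if self.exposure is not None:
            flag = self.exposure_flag
            if not flag.any():
                raise ValueError("exposure window does not overlap the series span")
            idx = np.flatnonzero(flag)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError("exposure flag must be one contiguous block")

    @property
    def periods(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def t(self) -> np.ndarray:
        """0-based sequential period index."""
        return np.arange(len(self.counts))

    @property
    def exposure_flag(self) -> np.ndarray:
        if self.exposure is None:
            return np.zeros(len(self.counts), dtype=bool)
        window = set(self.exposure.periods(self.frequency))
        return np.array([p in window for p in self.counts.index], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Tidy ``period,group,count`` table."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["period", "group", "count"]
        return long

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, frequency: str,
                   exposure: ExposureWindow | None = None) -> "GroupedCountSeries":
        """Build from a tidy ``period,group,count`` table, zero-filling."""
        required = {"period", "group", "count"}
        if not required.issubset(frame.columns):
            raise ValueError(f"count table must have columns {sorted(required)}")
        wide = frame.pivot_table(index="period", columns="group", values="count",
                                 aggfunc="sum", fill_value=0)
        labels = sorted(wide.index, key=lambda p: parse_period(p, frequency))
        full = period_range(labels[0], labels[-1], frequency)
        wide = wide.reindex(full, fill_value=0)
        wide.columns.name = None
        wide.index.name = "period"
        return cls(frequency=frequency, counts=wide, exposure=exposure)

    @classmethod
    def read_csv(cls, path, frequency: str,
                 exposure: ExposureWindow | None = None) -> "GroupedCountSeries":
        return cls.from_frame(pd.read_csv(path, dtype={"period": str, "group": str}),
                              frequency, exposure)


# ---------------------------------------------------------------------------
# Record-level operations
# ---------------------------------------------------------------------------

def _parse_dates(records: pd.DataFrame) -> pd.Series:
    if "date_of_birth" not in records.columns:
        raise ValueError("records must have a 'date_of_birth' column")
    parsed = pd.to_datetime(records["date_of_birth"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & records["date_of_birth"].notna()
    if parsed.isna().any():
        pos = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable date_of_birth at record position {pos}: "
            f"{records['date_of_birth'].iloc[pos]!r}")
    return parsed.dt.date


def aggregate_records(records: pd.DataFrame, frequency: str,
                      group_rule: Callable[[pd.DataFrame], pd.Series] | str | None = None,
                      exposure: ExposureWindow | None = None) -> GroupedCountSeries:
    """Aggregate individual birth records into a grouped count series.

    Parameters
    ----------
    records
        One row per live birth with a ``date_of_birth`` column
        (ISO ``YYYY-MM-DD``) plus whatever fields the group rule needs.
    group_rule
        Either the name of a column holding group labels (default
        ``"group"``), or a callable mapping the records frame to a
        Series of labels (e.g. quintile assignment).
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    check_frequency(frequency)
    dates = _parse_dates(records)
    if group_rule is None:
        group_rule = "group"
    if callable(group_rule):
        labels = pd.Series(group_rule(records), index=records.index).astype(str)
    else:
        if group_rule not in records.columns:
            raise ValueError(f"group column {group_rule!r} not present in records")
        labels = records[group_rule].astype(str)
    periods = [period_of_date(d, frequency) for d in dates]
    tidy = pd.DataFrame({"period": periods, "group": labels.to_numpy(), "count": 1})
    return GroupedCountSeries.from_frame(tidy, frequency, exposure=exposure)


def assign_quintiles(values: Sequence[float] | pd.Series,
                     reference: Sequence[float] | pd.Series,
                     missing_label: str = MISSING_LABEL) -> pd.Series:
    """Categorise continuous socioeconomic scores into quintiles Q1..Q5.

    Cutpoints are the 20/40/60/80 percentiles of the *reference*
    (pre-pandemic) distribution only, so pandemic-era shifts in the
    score distribution cannot move the group boundaries.  Q5 is the
    highest-score (most advantaged) quintile.  Values equal to a
    cutpoint fall in the lower quintile; missing values get
    ``missing_label``.
    """
    ref = pd.Series(reference, dtype=float).dropna()
    if ref.empty:
        raise ValueError("reference distribution is empty or all-missing")
    cuts = np.percentile(ref.to_numpy(), [20, 40, 60, 80])
    vals = pd.Series(values, dtype=float)
    # value <= cutpoint -> lower quintile (left-closed convention)
    idx = np.searchsorted(cuts, vals.to_numpy(), side="left")
    labels = pd.Series([f"Q{i + 1}" for i in idx], index=vals.index, dtype=object)
    labels[vals.isna()] = missing_label
    return labels


_FILTER_OPS = {
    "gt": np.greater, "ge": np.greater_equal,
    "lt": np.less, "le": np.less_equal, "eq": np.equal,
}


def filter_records(records: pd.DataFrame, predicate_config: dict | None) -> pd.DataFrame:
    """Drop records failing the configured predicates.

    ``predicate_config`` maps field name to ``{op: value}`` with op in
    gt/ge/lt/le/eq/in, e.g. ``{"maternal_age": {"gt": 25}}`` for the
    over-25 maternal-age restriction (strictly greater than 25).
    An empty/None config is the identity.
    """
    if not predicate_config:
        return records
    keep = pd.Series(True, index=records.index)
    for fieldname, ops in predicate_config.items():
        if fieldname not in records.columns:
            raise ValueError(f"filter references absent field {fieldname!r}")
        col = records[fieldname]
        for op, value in ops.items():
            if op == "in":
                keep &= col.isin(value)
            elif op in _FILTER_OPS:
                keep &= pd.Series(_FILTER_OPS[op](col, value), index=records.index).fillna(False)
            else:
                raise ValueError(f"unknown filter op {op!r}")
    removed = int((~keep).sum())
    logger.info("filter_records: removed %d of %d records", removed, len(records))
    return records.loc[keep]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def scaled_time(n_periods: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred/scaled linear and quadratic time covariates.

    ``t_lin = (t - mean(t)) / n`` keeps the quadratic term well
    conditioned on multi-year series.
    """
    t = np.arange(n_periods, dtype=float)
    t_lin = (t - t.mean()) / n_periods
    return t_lin, t_lin ** 2


def season_column_name(level: int, frequency: str) -> str:
    return f"season_w{level:02d}" if frequency == WEEKLY else f"season_m{level:02d}"


def build_design_matrix(series: GroupedCountSeries, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix for the per-group ITS Poisson regression.

    Columns: ``intercept``, ``t_lin``, ``t_quad``, one indicator per
    non-reference week/month of the year (week 53 merged with 52), one
    indicator per shock window, and the ``exposure`` indicator.  There
    is no population-at-risk offset.  Seasonal levels absent from the
    data span are dropped with a warning.
    """
    freq = series.frequency
    periods = series.periods
    span = set(periods)
    for shock in spec.shocks:
        if shock.start not in span or shock.end not in span:
            raise ValueError(f"shock window {shock.label!r} lies outside the series span")
    if spec.exposure.start not in span or spec.exposure.end not in span:
        raise ValueError(
            f"exposure window {spec.exposure.start}..{spec.exposure.end} "
            "lies outside the series span")
    exposed = set(spec.exposure.periods(freq))
    for shock in spec.shocks:
        if exposed & set(shock.periods(freq)):
            raise ValueError(f"shock window {shock.label!r} overlaps the exposure window")

    n = len(periods)
    t_lin, t_quad = scaled_time(n)
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(n),
        "t_lin": t_lin,
        "t_quad": t_quad,
    }
    levels = np.array([seasonal_level(p, freq) for p in periods])
    cycle = range(1, 53) if freq == WEEKLY else range(1, 13)
    present = set(levels)
    for lvl in cycle:
        if lvl == spec.seasonal_reference:
            continue
        if lvl not in present:
            warnings.warn(
                f"seasonal level {lvl} absent from data span; column dropped",
                UserWarning, stacklevel=2)
            continue
        cols[season_column_name(lvl, freq)] = (levels == lvl).astype(float)
    for shock in spec.shocks:
        window = set(shock.periods(freq))
        cols[f"shock_{shock.label}"] = np.array([p in window for p in periods], dtype=float)
    cols["exposure"] = np.array([p in exposed for p in periods], dtype=float)
    return pd.DataFrame(cols, index=pd.Index(periods, name="period"))
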