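"""Shared fixtures: small synthetic scenarios and fixtured fits."""

import numpy as np
import pytest

from cohortshift import (
    ExposureWindow,
    GroupTruth,
    ModelSpec,
    SyntheticScenario,
)


def monthly_seasonal():
    """A mild 12-month seasonal pattern, reference month fixed at 0."""
    s = 0.08 * np.sin(2 * np.pi * np.arange(12) / 12)
    s[0] = 0.0
    return s


@pytest.fixture
def flat_scenario():
    """One group, constant mean 100, no trend/season/exposure, 200 months."""
    return SyntheticScenario(
        frequency="monthly",
        start_period="2005-05",
        end_period="2021-12",
        groups={"A": GroupTruth(intercept=np.log(100.0))},
        seed=42,
    )


@pytest.fixture
def two_group_scenario():
    """Two groups, monthly 2015-2021, group A has a +10% exposure effect."""
    return SyntheticScenario(
        frequency="monthly",
        start_period="2015-01",
        end_period="2021-12",
        groups={
            "A": GroupTruth(intercept=np.log(800.0), trend_lin=0.15,
                            trend_quad=-0.3, seasonal=monthly_seasonal(),
                            exposure_effect=np.log(1.10)),
            "B": GroupTruth(intercept=np.log(600.0), trend_lin=-0.1,
                            seasonal=monthly_seasonal()),
        },
        seed=7,
    )


@pytest.fixture
def null_scenario():
    """Two groups, no exposure effect anywhere (true deltas are 0)."""
    return SyntheticScenario(
        frequency="monthly",
        start_period="2015-01",
        end_period="2021-12",
        groups={
            "A": GroupTruth(intercept=np.log(700.0), trend_lin=0.1,
                            seasonal=monthly_seasonal()),
            "B": GroupTruth(intercept=np.log(500.0), trend_lin=-0.05,
                            seasonal=monthly_seasonal()),
        },
        seed=11,
    )


@pytest.fixture
def weekly_scenario():
    """Weekly two-group scenario spanning 2015-2021 with a Zika-style dip."""
    seasonal = 0.05 * np.cos(2 * np.pi * np.arange(52) / 52)
    seasonal[0] = 0.0
    from cohortshift import ShockWindow
    return SyntheticScenario(
        frequency="weekly",
        start_period="2015-W01",
        end_period="2021-W52",
        groups={
            "adv": GroupTruth(intercept=np.log(400.0), trend_lin=0.1,
                              seasonal=seasonal, exposure_effect=np.log(1.07),
                              shock_effects={"zika": -0.1}),
            "dis": GroupTruth(intercept=np.log(400.0), seasonal=seasonal,
                              shock_effects={"zika": -0.15}),
        },
        shock_windows=(ShockWindow("zika", "2016-W31", "2016-W52"),),
        seed=5,
    )
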