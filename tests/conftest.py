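import warnings

import numpy as np
import pandas as pd
import pytest

import flexcure as fc


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*negative fitted excess.*")
        warnings.filterwarnings("ignore", message=".*non-positive fitted total.*")
        yield


@pytest.fixture(scope="session")
def recovery_sim():
    """One mid-size single-pattern cohort with known cure structure."""
    spec = fc.recovery_scenario(pi=0.5, n=4000, seed=42)
    return fc.simulate_cohort(spec)


@pytest.fixture(scope="session")
def twogroup_sim():
    """Two age groups with a proportional excess hazard contrast (exact under
    non-mixture truth: a shift on the log(-log) cure scale shifts the whole
    log cumulative excess hazard)."""
    spec = fc.ScenarioSpec(
        n=6000, family="nonmixture", pi=0.5,
        uncured={"dist": "weibull", "scale": 1.1, "shape": 1.2},
        age_groups=(("A", 55.0, 65.0, 0.5), ("B", 65.0, 75.0, 0.5)),
        pi_age_effects={"B": 0.5}, seed=17)
    return fc.simulate_cohort(spec)


def _y(df):
    return df["time"].to_numpy(), df["event"].to_numpy()


@pytest.fixture(scope="session")
def fitted_cure(recovery_sim):
    m = fc.FlexibleParametricModel(cure=True, ratetable=recovery_sim.ratetable)
    return m.fit(recovery_sim.data, _y(recovery_sim.data))


@pytest.fixture(scope="session")
def fitted_unrestricted(recovery_sim):
    m = fc.FlexibleParametricModel(cure=False, direction="backward",
                                   ratetable=recovery_sim.ratetable)
    return m.fit(recovery_sim.data, _y(recovery_sim.data))


@pytest.fixture(scope="session")
def fitted_nonmixture(recovery_sim):
    m = fc.WeibullCureModel(kind="nonmixture", ratetable=recovery_sim.ratetable)
    return m.fit(recovery_sim.data, _y(recovery_sim.data))


@pytest.fixture()
def zero_ratetable():
    """All expected rates zero: pure net-survival setting."""
    rows = [(a, y, "male", 0.0) for a in range(40, 100) for y in (1990, 1991)]
    return fc.RateTable(pd.DataFrame(rows, columns=["age", "year", "sex", "rate"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
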