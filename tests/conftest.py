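import numpy as np
import pandas as pd
import pytest

import oxbal


@pytest.fixture(scope="session")
def tiny_cohort():
    return oxbal.load_packaged_fixture("tiny")


@pytest.fixture(scope="session")
def small_analytic():
    """A clean scored analytic table (n=1500) shared across pipeline tests."""
    cfg = oxbal.SimulationConfig(n=1500, seed=77, prevalent_ascvd_prob=0.0, baseline_hazard=0.005)
    df = oxbal.generate_cohort(cfg)
    analytic, ledger = oxbal.prepare_analytic_table(df)
    return analytic, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def logistic_sim():
    """iid logistic data with known coefficients for solver tests."""
    r = np.random.default_rng(5)
    n = 2000
    x1 = r.normal(size=n)
    x2 = r.binomial(1, 0.4, n).astype(float)
    lp = -0.4 + 0.7 * x1 - 0.5 * x2
    y = (r.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    X = pd.DataFrame({"intercept": np.ones(n), "x1": x1, "x2": x2})
    return y, X


@pytest.fixture(scope="session")
def cox_sim():
    """iid censored exponential survival data, continuous covariates (no ties)."""
    r = np.random.default_rng(6)
    n = 2000
    x1 = r.normal(size=n)
    x2 = r.normal(size=n)
    lam = 0.5 * np.exp(0.6 * x1 - 0.3 * x2)
    t = r.exponential(1 / lam)
    c = r.exponential(4.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(float)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    return time, event, X
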