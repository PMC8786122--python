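import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import colonycensus as cc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def default_params() -> cc.YearParams:
    """Reference site-year: mid-January arrival, month-long tenure."""
    return cc.YearParams(
        N=1000.0, a_mean=45.0, a_sd=10.0, corr=0.0,
        tenure_mean=31.06, tenure_cv=0.1212,
    )


@pytest.fixture
def fixed_tenure_params() -> cc.YearParams:
    """Analytic limit: every female stays exactly tenure_mean days."""
    return cc.YearParams(
        N=1000.0, a_mean=45.0, a_sd=10.0, corr=0.0,
        tenure_mean=31.06, tenure_cv=0.0,
    )


def degenerate_draws(p: cc.YearParams, years=(2015,), n=200, site="DEG"):
    """PosteriorDraws concentrated on a single parameter point."""
    row = np.array([p.N, p.a_mean, p.a_sd, p.corr, p.tenure_mean, p.tenure_cv])
    year_draws = np.tile(row, (1, n, len(years), 1))
    hyper = np.array([p.a_mean, 1e-3, p.a_sd, 1e-3, p.corr, 1e-3])
    hyper_draws = np.tile(hyper, (1, n, 1))
    return cc.PosteriorDraws(
        site=site,
        years=list(years),
        year_draws=year_draws,
        hyper_draws=hyper_draws,
        fixed_hypers={"mu_d": 31.06, "sigma_d": 0.27, "mu_v": 0.1212, "sigma_v": 0.0062},
        acceptance={},
        rhat={},
        converged=True,
        meta={},
    )
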