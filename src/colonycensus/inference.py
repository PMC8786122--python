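"""Hierarchical Bayesian fit of the census model to multi-year count series.

All seasons of counts at one site are fitted jointly, with season (year) as
a random effect.  Each year *i* carries the six census-curve parameters
(N_i, a_mean_i, a_sd_i, corr_i, tenure_mean_i, tenure_cv_i); the five
timing parameters are tied across years by Gaussian hyper-distributions
(mean arrival, arrival SD and arrival-tenure correlation have estimated
hyper-means and hyper-SDs; mean tenure and tenure CV have narrow priors
fixed in advance at 31.06 +/- 0.27 d and 0.1212 +/- 0.0062).  The annual
population sizes N_i are unconstrained.  A model over Y years therefore has
6Y + 10 parameters, four of them fixed constants.

Sampling is adaptive Metropolis-within-Gibbs: one block per year's six
parameters (updated component-wise) plus one hyper block, with proposal
scales adapted during burn-in to keep acceptance near 0.2-0.4.  The
correlation is proposed on the Fisher-z scale so moves stay inside (-1, 1).
Counts are modelled as Poisson around the census curve C(t) by default,
with a Gaussian-CV alternative.

The hierarchy is what lets data-poor years be kept: a year with only a
handful of counts borrows its arrival timing from the hyper-distribution
estimated from the data-rich years.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .model_core import SEASON_END, SEASON_START, YearParams, from_season_day

__all__ = [
    "HyperParams",
    "FitConfig",
    "PosteriorDraws",
    "log_likelihood",
    "fit_site",
    "summarize",
    "timing_summary",
    "compare_intervals",
    "day_label",
]

logger = logging.getLogger(__name__)

#: fixed narrow priors on the tenure parameters (mean tenure in days; CV)
MU_D, SIGMA_D = 31.06, 0.27
MU_V, SIGMA_V = 0.1212, 0.0062

#: order of the six per-year parameters everywhere in this package
YEAR_PARAM_NAMES = ("N", "a_mean", "a_sd", "corr", "tenure_mean", "tenure_cv")
#: order of the six estimated hyper-parameters
HYPER_PARAM_NAMES = ("mu_a", "sigma_a", "mu_s", "sigma_s", "mu_c", "sigma_c")
FIXED_HYPER_NAMES = ("mu_d", "sigma_d", "mu_v", "sigma_v")


@dataclass(frozen=True)
class HyperParams:
    """Across-year hyper-distribution of the per-year census parameters.

    ``mu_a/sigma_a`` govern mean arrival date, ``mu_s/sigma_s`` the arrival
    SD and ``mu_c/sigma_c`` the arrival-tenure correlation.  The tenure
    hyper-values default to the fixed narrow priors and rarely need
    changing.  Ten values in all.
    """

    mu_a: float
    sigma_a: float
    mu_s: float
    sigma_s: float
    mu_c: float = 0.0
    sigma_c: float = 0.2
    mu_d: float = MU_D
    sigma_d: float = SIGMA_D
    mu_v: float = MU_V
    sigma_v: float = SIGMA_V

    def __post_init__(self) -> None:
        for name in ("sigma_a", "sigma_s", "sigma_c", "sigma_d", "sigma_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings and priors for :func:`fit_site`."""

    chains: int = 4
    iterations: int = 20_000
    burn_frac: float = 0.5
    thin: int = 10
    seed: int = 0
    noise: str = "poisson"  # or "gaussian_cv"
    noise_scale: float = 0.1  # CV of the gaussian_cv noise model
    # hyper priors: half-Gaussian scales on the hyper-SDs, flat hyper-means
    sigma_a_prior_scale: float = 10.0
    sigma_s_prior_scale: float = 10.0
    sigma_c_prior_scale: float = 0.5
    n_max: float = 1e7
    # fixed tenure priors, overridable via config only
    mu_d: float = MU_D
    sigma_d: float = SIGMA_D
    mu_v: float = MU_V
    sigma_v: float = SIGMA_V
    adapt_window: int = 50
    rhat_limit: float = 1.05

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 20:
            raise ValueError("need at least 1 chain and 20 iterations")
        if not 0 < self.burn_frac < 1:
            raise ValueError("burn_frac must be in (0, 1)")
        if self.noise not in ("poisson", "gaussian_cv"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def burn_in(self) -> int:
        return int(self.iterations * self.burn_frac)


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned MCMC draws for one site.

    ``year_draws`` has shape (chains, draws, Y, 6) in the order of
    :data:`YEAR_PARAM_NAMES` (the correlation is stored as a correlation,
    not on the Fisher-z scale); ``hyper_draws`` has shape
    (chains, draws, 6) in the order of :data:`HYPER_PARAM_NAMES`.
    """

    site: str
    years: list[int]
    year_draws: np.ndarray
    hyper_draws: np.ndarray
    fixed_hypers: dict[str, float]
    acceptance: dict[str, float]
    rhat: dict[str, float]
    converged: bool
    meta: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        """Total parameter count of the fitted model: 6Y + 10."""
        return 6 * len(self.years) + 10

    @property
    def n_draws(self) -> int:
        return self.year_draws.shape[0] * self.year_draws.shape[1]

    def param_names(self) -> list[str]:
        names = [
            f"{p}[{y}]" for y in self.years for p in YEAR_PARAM_NAMES
        ]
        names += list(HYPER_PARAM_NAMES) + list(FIXED_HYPER_NAMES)
        return names

    def to_frame(self) -> pd.DataFrame:
        """Stack all chains into one draw-per-row table, one parameter per
        column, with a leading ``chain`` column."""
        nc, nd, ny, _ = self.year_draws.shape
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(nc), nd),
        }
        for j, y in enumerate(self.years):
            for k, p in enumerate(YEAR_PARAM_NAMES):
                cols[f"{p}[{y}]"] = self.year_draws[:, :, j, k].reshape(-1)
        for k, p in enumerate(HYPER_PARAM_NAMES):
            cols[p] = self.hyper_draws[:, :, k].reshape(-1)
        for p in FIXED_HYPER_NAMES:
            cols[p] = np.full(nc * nd, self.fixed_hypers[p])
        return pd.DataFrame(cols)

    def year_params(self, chain: int, draw: int, year: int) -> YearParams:
        j = self.years.index(year)
        n, a, s, c, d, v = self.year_draws[chain, draw, j]
        return YearParams(N=n, a_mean=a, a_sd=s, corr=c, tenure_mean=d, tenure_cv=v)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _curve_at(days, theta):
    """C(t) at observed days for theta = (N, a, s, c, d, v); None if invalid."""
    n, a, s, c, d, v = theta
    var = s * s + (v * d) ** 2 + 2.0 * c * s * v * d
    if var <= 0.0:
        return None
    return n * (ndtr((days - a) / s) - ndtr((days - a - d) / math.sqrt(var)))


def _year_loglik(days, obs, lgam, theta, noise, noise_scale):
    c = _curve_at(days, theta)
    if c is None:
        return -np.inf
    if noise == "poisson":
        c = np.maximum(c, 1e-12)
        return float(np.sum(obs * np.log(c) - c - lgam))
    sd = np.maximum(noise_scale * c, 1e-6)
    return float(np.sum(-np.log(sd) - 0.5 * ((obs - c) / sd) ** 2))


def log_likelihood(
    counts: Mapping[int, pd.Series],
    params: Mapping[int, YearParams],
    noise: str = "poisson",
    noise_scale: float = 0.1,
) -> float:
    """Joint log-likelihood of the observed counts given per-year parameters.

    ``counts`` maps season label to a Series of counts indexed by season
    day; ``params`` maps the same seasons to :class:`YearParams`.  The
    count-error model is Poisson(observed | C(t)) by default.
    """
    total = 0.0
    for year, series in counts.items():
        p = params[year]
        days = np.asarray(series.index, dtype=float)
        if days.size and (days.min() < SEASON_START or days.max() > SEASON_END):
            raise ValueError(f"season {year}: observed days outside window")
        obs = np.asarray(series.values, dtype=float)
        lgam = gammaln(obs + 1.0)
        theta = (p.N, p.a_mean, p.a_sd, p.corr, p.tenure_mean, p.tenure_cv)
        total += _year_loglik(days, obs, lgam, theta, noise, noise_scale)
    return total


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

_LNORM_CONST = -0.5 * math.log(2.0 * math.pi)


def _lnorm(x, m, s):
    return -math.log(s) - 0.5 * ((x - m) / s) ** 2


# bounds for the six per-year state components [N, a, s, z, d, v]
_YEAR_LO = np.array([1e-6, SEASON_START - 60.0, 1e-2, -5.0, 1e-2, 1e-6])
_YEAR_HI = np.array([1e7, SEASON_END + 60.0, 60.0, 5.0, 120.0, 2.0])


def _year_prior_term(k, x, hyper, cfg):
    """Log-prior contribution of component k of a year state.

    Component 3 is Fisher-z of the correlation; the Gaussian hyper-prior
    applies to the correlation itself, so the tanh Jacobian appears here.
    """
    if k == 0:
        return 0.0  # N flat on (0, n_max)
    if k == 1:
        return _lnorm(x, hyper[0], hyper[1])
    if k == 2:
        return _lnorm(x, hyper[2], hyper[3])
    if k == 3:
        c = math.tanh(x)
        return _lnorm(c, hyper[4], hyper[5]) + math.log1p(-c * c)
    if k == 4:
        return _lnorm(x, cfg.mu_d, cfg.sigma_d)
    return _lnorm(x, cfg.mu_v, cfg.sigma_v)


# bounds for hyper state [mu_a, sigma_a, mu_s, sigma_s, mu_c, sigma_c]
_HYPER_LO = np.array([SEASON_START - 60.0, 1e-3, 1e-2, 1e-3, -0.999, 1e-4])
_HYPER_HI = np.array([SEASON_END + 60.0, 60.0, 60.0, 60.0, 0.999, 5.0])


def _hyper_prior_term(k, x, cfg):
    if k == 1:
        return -0.5 * (x / cfg.sigma_a_prior_scale) ** 2
    if k == 3:
        return -0.5 * (x / cfg.sigma_s_prior_scale) ** 2
    if k == 5:
        return -0.5 * (x / cfg.sigma_c_prior_scale) ** 2
    return 0.0  # flat hyper-means inside bounds


def _weighted_init(days, obs, cfg):
    """Moment-based starting point for one year's parameters."""
    tot = obs.sum()
    if tot > 0:
        wmean = float(np.sum(days * obs) / tot)
        wvar = float(np.sum(obs * (days - wmean) ** 2) / tot)
    else:  # all-zero counts: start mid-window
        wmean, wvar = 60.0, 150.0
    a = wmean - cfg.mu_d / 2.0
    # count-weighted day variance ~ arrival var + tenure^2 / 12
    s = math.sqrt(max(wvar - cfg.mu_d ** 2 / 12.0, 9.0))
    n = max(float(obs.max(initial=0.0)) * 1.15, 1.0)
    return np.array([n, a, min(s, 30.0), 0.0, cfg.mu_d, cfg.mu_v])


def _run_chain(data, cfg, seed):
    """One MCMC chain; returns (year_out, hyper_out, acceptance dict)."""
    rng = np.random.default_rng(seed)
    Y = len(data)
    # --- initial state, jittered per chain for overdispersed starts
    year = np.empty((Y, 6))
    for i, (days, obs, _) in enumerate(data):
        year[i] = _weighted_init(days, obs, cfg)
        year[i, 0] *= math.exp(rng.normal(0.0, 0.05))
        year[i, 1] += rng.normal(0.0, 1.0)
        year[i, 2] *= math.exp(rng.normal(0.0, 0.1))
        year[i, 4] += rng.normal(0.0, cfg.sigma_d)
        year[i, 5] += rng.normal(0.0, cfg.sigma_v)
    hyper = np.array(
        [
            float(np.mean(year[:, 1])),
            max(float(np.std(year[:, 1])), 1.0),
            float(np.mean(year[:, 2])),
            1.0,
            0.0,
            0.2,
        ]
    )
    hyper[0] += rng.normal(0.0, 0.5)
    year = np.clip(year, _YEAR_LO, _YEAR_HI * 0.999)
    hyper = np.clip(hyper, _HYPER_LO, _HYPER_HI * 0.999)

    ll = np.array(
        [
            _year_loglik(d, o, g, _to_theta(year[i]), cfg.noise, cfg.noise_scale)
            for i, (d, o, g) in enumerate(data)
        ]
    )

    # proposal scales and acceptance bookkeeping
    ysc = np.tile([0.1, 1.0, 0.5, 0.2, 0.2, 0.005], (Y, 1))
    ysc[:, 0] = 0.1 * year[:, 0]
    hsc = np.array([0.5, 0.3, 0.5, 0.3, 0.05, 0.05])
    yacc = np.zeros((Y, 6)); yatt = np.zeros((Y, 6))
    hacc = np.zeros(6); hatt = np.zeros(6)
    post_yacc = np.zeros((Y, 6)); post_yatt = np.zeros((Y, 6))
    post_hacc = np.zeros(6); post_hatt = np.zeros(6)

    burn = cfg.burn_in
    n_store = (cfg.iterations - burn + cfg.thin - 1) // cfg.thin
    year_out = np.empty((n_store, Y, 6))
    hyper_out = np.empty((n_store, 6))
    stored = 0

    for it in range(cfg.iterations):
        adapting = it < burn
        # --- per-year blocks, component-wise random-walk Metropolis
        for i in range(Y):
            days, obs, lgam = data[i]
            th = year[i]
            for k in range(6):
                old = th[k]
                new = old + ysc[i, k] * rng.standard_normal()
                yatt[i, k] += 1
                if not adapting:
                    post_yatt[i, k] += 1
                if not _YEAR_LO[k] < new < _YEAR_HI[k]:
                    continue
                dprior = _year_prior_term(k, new, hyper, cfg) - _year_prior_term(
                    k, old, hyper, cfg
                )
                th[k] = new
                new_ll = _year_loglik(
                    days, obs, lgam, _to_theta(th), cfg.noise, cfg.noise_scale
                )
                if math.log(rng.random()) < new_ll - ll[i] + dprior:
                    ll[i] = new_ll
                    yacc[i, k] += 1
                    if not adapting:
                        post_yacc[i, k] += 1
                else:
                    th[k] = old
        # --- hyper block (no data likelihood: conditionally independent)
        cvec = np.tanh(year[:, 3])
        col = {0: year[:, 1], 1: year[:, 1], 2: year[:, 2], 3: year[:, 2], 4: cvec, 5: cvec}
        for k in range(6):
            old = hyper[k]
            new = old + hsc[k] * rng.standard_normal()
            hatt[k] += 1
            if not adapting:
                post_hatt[k] += 1
            if not _HYPER_LO[k] < new < _HYPER_HI[k]:
                continue
            x = col[k]
            m_idx = k - (k % 2)  # index of the mean paired with this sigma
            if k % 2 == 0:  # a hyper-mean moves
                dlp = float(
                    np.sum(-0.5 * ((x - new) / hyper[k + 1]) ** 2)
                    - np.sum(-0.5 * ((x - old) / hyper[k + 1]) ** 2)
                )
            else:  # a hyper-SD moves
                mu = hyper[m_idx]
                dlp = float(
                    np.sum(-math.log(new) - 0.5 * ((x - mu) / new) ** 2)
                    - np.sum(-math.log(old) - 0.5 * ((x - mu) / old) ** 2)
                )
            dlp += _hyper_prior_term(k, new, cfg) - _hyper_prior_term(k, old, cfg)
            if math.log(rng.random()) < dlp:
                hyper[k] = new
                hacc[k] += 1
                if not adapting:
                    post_hacc[k] += 1
        # --- adapt proposal scales during burn-in only
        if adapting and (it + 1) % cfg.adapt_window == 0:
            yrate = np.divide(yacc, np.maximum(yatt, 1))
            ysc *= np.where(yrate > 0.4, 1.4, np.where(yrate < 0.2, 0.7, 1.0))
            hrate = np.divide(hacc, np.maximum(hatt, 1))
            hsc *= np.where(hrate > 0.4, 1.4, np.where(hrate < 0.2, 0.7, 1.0))
            yacc[:] = 0; yatt[:] = 0; hacc[:] = 0; hatt[:] = 0
        # --- store
        if it >= burn and (it - burn) % cfg.thin == 0:
            out = year.copy()
            out[:, 3] = np.tanh(out[:, 3])
            year_out[stored] = out
            hyper_out[stored] = hyper
            stored += 1

    acc = {
        f"year[{i}]": float(post_yacc[i].sum() / max(post_yatt[i].sum(), 1))
        for i in range(Y)
    }
    acc["hyper"] = float(post_hacc.sum() / max(post_hatt.sum(), 1))
    return year_out[:stored], hyper_out[:stored], acc


def _to_theta(state):
    """Sampler state [N, a, s, z, d, v] -> curve parameters with corr."""
    return (state[0], state[1], state[2], math.tanh(state[3]), state[4], state[5])


def _split_rhat(x: np.ndarray) -> float:
    """Rank-normalized split-R-hat via arviz on a (chain, draw) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(x))


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_site(
    counts: Mapping[int, pd.Series],
    config: FitConfig | None = None,
    site: str = "site",
) -> PosteriorDraws:
    """Fit the multi-year hierarchical census model to one site's counts.

    Parameters
    ----------
    counts
        Mapping of season label -> Series of observed female counts indexed
        by season day (day 1 = 1 Dec).  Seasons with no counts are dropped
        with a warning; at least one season with at least one count is
        required.
    config
        MCMC settings; see :class:`FitConfig`.

    Returns
    -------
    PosteriorDraws
        Thinned post-burn-in draws of all 6Y + 10 parameters, acceptance
        rates per block, split-R-hat per sampled parameter and a
        ``converged`` flag (R-hat < 1.05 everywhere).  Non-convergence is
        flagged and logged, never silently ignored.
    """
    cfg = config or FitConfig()
    kept: dict[int, pd.Series] = {}
    for year in sorted(counts):
        series = counts[year].dropna()
        if len(series) == 0:
            logger.warning("season %s has no counts; excluded from the fit", year)
            continue
        days = np.asarray(series.index, dtype=float)
        if days.min() < SEASON_START or days.max() > SEASON_END:
            raise ValueError(
                f"season {year}: observed days outside the [{SEASON_START}, "
                f"{SEASON_END}] window"
            )
        kept[year] = series
    if not kept:
        raise ValueError("no season contains any counts")
    years = sorted(kept)
    data = []
    for year in years:
        obs = np.asarray(kept[year].values, dtype=float)
        days = np.asarray(kept[year].index, dtype=float)
        data.append((days, obs, gammaln(obs + 1.0)))
        if len(obs) < 5:
            logger.warning(
                "season %s has only %d counts; its timing will shrink toward "
                "the hyper-distribution",
                year,
                len(obs),
            )

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    year_chains, hyper_chains, accs = [], [], []
    for c in range(cfg.chains):
        yo, ho, acc = _run_chain(data, cfg, seeds[c])
        year_chains.append(yo)
        hyper_chains.append(ho)
        accs.append(acc)
        logger.info("chain %d/%d done (%d draws kept)", c + 1, cfg.chains, len(yo))
    year_draws = np.stack(year_chains)  # (chains, draws, Y, 6)
    hyper_draws = np.stack(hyper_chains)

    rhat: dict[str, float] = {}
    for j, y in enumerate(years):
        for k, p in enumerate(YEAR_PARAM_NAMES):
            rhat[f"{p}[{y}]"] = _split_rhat(year_draws[:, :, j, k])
    for k, p in enumerate(HYPER_PARAM_NAMES):
        rhat[p] = _split_rhat(hyper_draws[:, :, k])
    worst = max(rhat, key=lambda n: rhat[n])
    converged = bool(rhat[worst] < cfg.rhat_limit)
    if not converged:
        logger.warning(
            "convergence flag: split-R-hat %.3f on %s exceeds %.2f",
            rhat[worst], worst, cfg.rhat_limit,
        )

    acceptance = {
        key: float(np.mean([a[key] for a in accs])) for key in accs[0]
    }
    meta = {
        "site": site,
        "chains": cfg.chains,
        "iterations": cfg.iterations,
        "burn_in": cfg.burn_in,
        "thin": cfg.thin,
        "seed": cfg.seed,
        "noise": cfg.noise,
        "noise_scale": cfg.noise_scale,
        "n_counts": {int(y): int(len(kept[y])) for y in years},
    }
    return PosteriorDraws(
        site=site,
        years=[int(y) for y in years],
        year_draws=year_draws,
        hyper_draws=hyper_draws,
        fixed_hypers={
            "mu_d": cfg.mu_d, "sigma_d": cfg.sigma_d,
            "mu_v": cfg.mu_v, "sigma_v": cfg.sigma_v,
        },
        acceptance=acceptance,
        rhat=rhat,
        converged=converged,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _ci(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior median and 95% credible interval for every parameter.

    Fixed hyper-constants appear as rows whose median equals the constant.
    """
    rows = []
    nc, nd, ny, _ = draws.year_draws.shape
    for j, y in enumerate(draws.years):
        for k, p in enumerate(YEAR_PARAM_NAMES):
            med, lo, hi = _ci(draws.year_draws[:, :, j, k].reshape(-1))
            rows.append((f"{p}[{y}]", med, lo, hi))
    for k, p in enumerate(HYPER_PARAM_NAMES):
        med, lo, hi = _ci(draws.hyper_draws[:, :, k].reshape(-1))
        rows.append((p, med, lo, hi))
    for p in FIXED_HYPER_NAMES:
        v = draws.fixed_hypers[p]
        rows.append((p, v, v, v))
    return pd.DataFrame(rows, columns=["parameter", "median", "lo95", "hi95"]).set_index(
        "parameter"
    )


def peak_date_batch(a, s, c, d, v, resolution: float = 0.01) -> np.ndarray:
    """Vectorized census-curve peak day for arrays of timing parameters.

    Coarse 0.25-day grid to bracket the unimodal maximum, then a local
    grid at ``resolution`` (ties toward the earlier day).  N cancels from
    the argmax so only the five timing parameters enter.
    """
    a, s, c, d, v = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float)) for x in (a, s, c, d, v))
    )
    sd = np.sqrt(s**2 + (v * d) ** 2 + 2.0 * c * s * v * d)
    coarse = np.arange(SEASON_START, SEASON_END + 0.25, 0.25)
    cur = ndtr((coarse[None, :] - a[:, None]) / s[:, None]) - ndtr(
        (coarse[None, :] - (a + d)[:, None]) / sd[:, None]
    )
    t0 = coarse[np.argmax(cur, axis=1)]
    off = np.arange(-0.25, 0.25 + resolution / 2, resolution)
    grid = t0[:, None] + off[None, :]
    cur = ndtr((grid - a[:, None]) / s[:, None]) - ndtr(
        (grid - (a + d)[:, None]) / sd[:, None]
    )
    return grid[np.arange(len(a)), np.argmax(cur, axis=1)]


def day_label(day: float) -> str:
    """Render a season day as a month-day label on a non-leap calendar."""
    return from_season_day(2001, int(round(day))).strftime("%b %d")


def timing_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-year mean arrival and peak census date, plus the hyper-mean
    arrival, each as posterior median with 95% credible interval.

    Peak dates are computed per posterior draw by maximizing that draw's
    census curve, then summarized, so their intervals propagate the full
    joint posterior.  Day indices are also rendered as calendar labels.
    """
    rows = []
    nc, nd, ny, _ = draws.year_draws.shape
    flat = draws.year_draws.reshape(nc * nd, ny, 6)
    for j, y in enumerate(draws.years):
        med, lo, hi = _ci(flat[:, j, 1])
        rows.append(("mean_arrival", y, med, lo, hi))
        peaks = peak_date_batch(
            flat[:, j, 1], flat[:, j, 2], flat[:, j, 3], flat[:, j, 4], flat[:, j, 5]
        )
        med, lo, hi = _ci(peaks)
        rows.append(("peak_census", y, med, lo, hi))
    med, lo, hi = _ci(draws.hyper_draws[:, :, 0].reshape(-1))
    rows.append(("hyper_mean_arrival", None, med, lo, hi))
    out = pd.DataFrame(
        rows, columns=["quantity", "season", "median_day", "lo95_day", "hi95_day"]
    )
    for col in ("median_day", "lo95_day", "hi95_day"):
        out[col.replace("_day", "_date")] = [
            day_label(v) if SEASON_START <= v <= SEASON_END else "" for v in out[col]
        ]
    return out


def compare_intervals(
    a: tuple[float, float], b: tuple[float, float]
) -> str:
    """Classify two credible intervals as ``"distinct"`` or ``"overlapping"``.

    Non-overlap of 95% intervals is the working criterion for a
    statistically meaningful difference; intervals sharing only an endpoint
    count as overlapping (conservative).
    """
    lo_a, hi_a = a
    lo_b, hi_b = b
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("interval bounds must satisfy lower <= upper")
    return "distinct" if max(lo_a, lo_b) > min(hi_a, hi_b) else "overlapping"
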