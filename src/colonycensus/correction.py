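"""Correction-factor tables: from posterior draws to single-count estimates.

The correction factor on day ``t`` is ``m(t) = N / C(t)``, the multiplier
that converts a single-day female count into the season's total population.
To make a table usable in future years it must average over two sources of
variation: year-to-year differences in timing, and posterior uncertainty
within a year.  Following the fitted hierarchy, seasons are resampled with
replacement (default 30) and, within each sampled season, joint posterior
draws of the five timing parameters are taken (default 40); each of the
resulting simulations (default 1200) evaluates a census curve with the
population pinned at a reference size (default 1000, which cancels in the
multiplier) and yields one m(t) per day.  The table rows are the mean and
2.5/97.5% quantiles of those simulations.

Days where the curve has essentially no support produce absurd multipliers;
any simulation with C(t) below 5% of N is discarded for that day, and a day
where more than half the simulations are discarded is marked unusable
rather than reported.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model_core import CORRECTION_GUARD, SEASON_END, SEASON_START, to_season_day
from .inference import PosteriorDraws, day_label

__all__ = [
    "CorrectionTable",
    "PopulationEstimate",
    "correction_curve",
    "apply_correction",
    "optimal_window",
]

#: default table window: 1 Jan (day 32) through 28 Feb (day 90)
DEFAULT_WINDOW = (32, 90)


@dataclass
class CorrectionTable:
    """Per-day multipliers with 95% bands for one site.

    ``table`` has one row per calendar day with columns ``date`` (month-day
    label), ``day`` (season-day index), ``multiplier`` (mean), ``lo95``,
    ``hi95`` and ``usable``.
    """

    site: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def row_for_day(self, day: int) -> pd.Series:
        hit = self.table[self.table["day"] == int(day)]
        if hit.empty:
            raise KeyError(
                f"day {day} outside the table window "
                f"[{self.table['day'].min()}, {self.table['day'].max()}]"
            )
        return hit.iloc[0]

    def usable_days(self) -> np.ndarray:
        return self.table.loc[self.table["usable"], "day"].to_numpy()


@dataclass(frozen=True)
class PopulationEstimate:
    """A corrected single count: point estimate with 95% interval."""

    estimate: float
    lo95: float
    hi95: float
    multiplier: float
    day: int


def correction_curve(
    draws: PosteriorDraws,
    n_years: int = 30,
    n_draws: int = 40,
    n_ref: float = 1000.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    guard: float = CORRECTION_GUARD,
    seed: int = 0,
) -> CorrectionTable:
    """Build a per-day correction-factor table from a site's posterior.

    ``n_years`` seasons are sampled with replacement from the fitted
    seasons and ``n_draws`` joint posterior draws of the timing parameters
    are taken within each, for ``n_years * n_draws`` simulated census
    curves at population ``n_ref``.  A fixed ``seed`` reproduces the table
    exactly.
    """
    if draws.year_draws.size == 0:
        raise ValueError("posterior draws are empty")
    lo_day, hi_day = int(window[0]), int(window[1])
    if not (SEASON_START <= lo_day < hi_day <= SEASON_END):
        raise ValueError(f"window must be within [{SEASON_START}, {SEASON_END}]")
    rng = np.random.default_rng(seed)
    nc, nd, ny, _ = draws.year_draws.shape
    n_sim = n_years * n_draws

    year_idx = rng.integers(0, ny, size=n_years)
    flat = draws.year_draws.reshape(nc * nd, ny, 6)
    sims = np.empty((n_sim, 5))
    for j, yi in enumerate(year_idx):
        rows = rng.integers(0, nc * nd, size=n_draws)
        sims[j * n_draws : (j + 1) * n_draws] = flat[rows, yi, 1:6]

    a, s, c, d, v = sims.T
    sd = np.sqrt(s**2 + (v * d) ** 2 + 2.0 * c * s * v * d)
    days = np.arange(lo_day, hi_day + 1)
    curve = n_ref * (
        ndtr((days[None, :] - a[:, None]) / s[:, None])
        - ndtr((days[None, :] - (a + d)[:, None]) / sd[:, None])
    )
    valid = curve >= guard * n_ref
    mult = np.where(valid, n_ref / np.maximum(curve, 1e-12), np.nan)

    n_valid = valid.sum(axis=0)
    usable = n_valid > n_sim / 2
    mean = np.full(days.shape, np.nan)
    lo = np.full(days.shape, np.nan)
    hi = np.full(days.shape, np.nan)
    if usable.any():
        sub = mult[:, usable]
        mean[usable] = np.nanmean(sub, axis=0)
        lo[usable] = np.nanquantile(sub, 0.025, axis=0)
        hi[usable] = np.nanquantile(sub, 0.975, axis=0)
    table = pd.DataFrame(
        {
            "date": [day_label(t) for t in days],
            "day": days,
            "multiplier": mean,
            "lo95": lo,
            "hi95": hi,
            "n_valid": n_valid,
            "usable": usable,
        }
    )
    meta = {
        "site": draws.site,
        "n_year_samples": int(n_years),
        "n_draws_per_year": int(n_draws),
        "n_simulations": int(n_sim),
        "reference_N": float(n_ref),
        "guard": float(guard),
        "seed": int(seed),
        "window": [lo_day, hi_day],
        "fitted_years": list(draws.years),
    }
    return CorrectionTable(site=draws.site, table=table, meta=meta)


def _coerce_day(date, table: CorrectionTable) -> int:
    """Accept a season-day int, an ISO date, or a datetime.date."""
    if isinstance(date, (int, np.integer)):
        return int(date)
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    if isinstance(date, dt.date):
        return to_season_day(date)[1]
    raise TypeError(f"cannot interpret {date!r} as a calendar date or season day")


def apply_correction(count: float, date, table: CorrectionTable) -> PopulationEstimate:
    """Convert one female count into a total-population estimate.

    ``date`` may be an ISO calendar date or a season-day index.  Unusable
    dates (census curve support too thin) are refused with a message naming
    the nearest usable window.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    day = _coerce_day(date, table)
    row = table.row_for_day(day)
    if not row["usable"]:
        usable = table.usable_days()
        hint = (
            f"usable days run {day_label(usable.min())} to {day_label(usable.max())}"
            if usable.size
            else "no usable days in this table"
        )
        raise ValueError(
            f"{row['date']} (day {day}) is outside the usable census window; {hint}"
        )
    m = float(row["multiplier"])
    return PopulationEstimate(
        estimate=count * m,
        lo95=count * float(row["lo95"]),
        hi95=count * float(row["hi95"]),
        multiplier=m,
        day=day,
    )


def optimal_window(table: CorrectionTable, factor: float = 1.1) -> pd.DataFrame:
    """Days whose interval width is near-minimal: the best time to count.

    Returns the contiguous run of usable days, containing the
    narrowest-interval day, whose 95% band width stays within ``factor``
    times the minimum width.
    """
    usable = table.table[table.table["usable"]].reset_index(drop=True)
    if len(usable) < 7:
        raise ValueError("need at least 7 usable days to locate an optimal window")
    width = (usable["hi95"] - usable["lo95"]).to_numpy()
    best = int(np.argmin(width))
    limit = width[best] * factor
    lo = best
    while lo > 0 and width[lo - 1] <= limit and usable["day"][lo - 1] == usable["day"][lo] - 1:
        lo -= 1
    hi = best
    while (
        hi < len(usable) - 1
        and width[hi + 1] <= limit
        and usable["day"][hi + 1] == usable["day"][hi] + 1
    ):
        hi += 1
    return usable.iloc[lo : hi + 1].reset_index(drop=True)
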