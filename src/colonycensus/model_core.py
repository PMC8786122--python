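"""Closed-form census curve for a seasonal breeding aggregation.

A colony of seasonal breeders (the motivating case is female northern
elephant seals hauled out to pup) is never fully ashore on any one day:
individuals arrive over a few weeks, stay for a roughly month-long tenure,
and leave again.  The expected number present on day ``t`` of a season is

    C(t) = A(t) - D(t)

where ``A(t)`` is the expected cumulative number arrived by ``t`` and
``D(t)`` the expected cumulative number departed.  Arrival dates are
Gaussian with mean ``a_mean`` and SD ``a_sd``; each individual's departure
is its arrival plus a Gaussian tenure (mean ``tenure_mean``, SD
``tenure_cv * tenure_mean``) that may be correlated with arrival date
(``corr``).  Because the pair (arrival, tenure) is bivariate Gaussian, the
departure date arrival + tenure is itself Gaussian and both cumulative
curves are scaled normal CDFs:

    A(t) = N * Phi((t - a_mean) / a_sd)
    D(t) = N * Phi((t - a_mean - tenure_mean) / sigma_D)
    sigma_D^2 = a_sd^2 + (tenure_cv * tenure_mean)^2
                + 2 * corr * a_sd * tenure_cv * tenure_mean

The superpopulation ``N`` (total distinct females using the site in one
season) therefore exceeds every single-day count; the correction factor
``m(t) = N / C(t)`` converts a count on day ``t`` into an estimate of N.

Season-day convention: day 1 is 1 December of the calendar year preceding
the season label; the season is labelled by the calendar year containing
its January (season 2018 spans Dec 2017 - Mar 2018, so 14 Jan 2018 is
day 45).  All curves are evaluated on the window [1, 120].
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

__all__ = [
    "SEASON_START",
    "SEASON_END",
    "YearParams",
    "CensusCurve",
    "OutsideCensusWindowError",
    "season_of_date",
    "to_season_day",
    "from_season_day",
    "cumulative_arrival",
    "cumulative_departure",
    "census",
    "census_curve",
    "peak_date",
    "correction_factor",
]

#: modeling window in season days (1 Dec through 30 Mar of a non-leap season)
SEASON_START = 1
SEASON_END = 120

#: default floor on C(t)/N below which a correction factor is refused
CORRECTION_GUARD = 0.05


class OutsideCensusWindowError(ValueError):
    """Raised when a correction factor is requested where C(t) is too small."""


# ---------------------------------------------------------------------------
# season-day calendar convention
# ---------------------------------------------------------------------------

def season_of_date(date: dt.date) -> int:
    """Season label (calendar year of the season's January) for a date.

    December dates belong to the following year's season; January-March
    dates to their own year's.
    """
    return date.year + 1 if date.month == 12 else date.year


def to_season_day(date: dt.date, season: int | None = None) -> tuple[int, int]:
    """Map a calendar date to ``(season, day_index)``.

    Raises ``ValueError`` if the date falls outside the [1, 120] window of
    its season (roughly December through March).
    """
    if season is None:
        season = season_of_date(date)
    day = (date - dt.date(season - 1, 12, 1)).days + 1
    if not SEASON_START <= day <= SEASON_END:
        raise ValueError(
            f"date {date.isoformat()} is day {day} of season {season}, outside "
            f"the modeling window [{SEASON_START}, {SEASON_END}] "
            "(day 1 = 1 December preceding the season's January)"
        )
    return season, day


def from_season_day(season: int, day: int) -> dt.date:
    """Inverse of :func:`to_season_day` for integer days."""
    if not SEASON_START <= day <= SEASON_END:
        raise ValueError(f"day {day} outside window [{SEASON_START}, {SEASON_END}]")
    return dt.date(season - 1, 12, 1) + dt.timedelta(days=int(day) - 1)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YearParams:
    """The six parameters of the census model for one site-season.

    Attributes
    ----------
    N : float
        Total breeding females using the site over the season (expected
        count scale; the superpopulation).
    a_mean : float
        Mean arrival date, in season days.
    a_sd : float
        SD of arrival date, days.
    corr : float
        Correlation between an individual's arrival date and its tenure,
        in (-1, 1).
    tenure_mean : float
        Mean tenure (continuous days ashore).
    tenure_cv : float
        Coefficient of variation of tenure (SD / mean); 0 gives the
        fixed-tenure analytic limit.
    """

    N: float
    a_mean: float
    a_sd: float
    corr: float
    tenure_mean: float
    tenure_cv: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"N must be > 0, got {self.N}")
        if not self.a_sd > 0:
            raise ValueError(f"a_sd must be > 0, got {self.a_sd}")
        if not self.tenure_mean > 0:
            raise ValueError(f"tenure_mean must be > 0, got {self.tenure_mean}")
        if not self.tenure_cv >= 0:
            raise ValueError(f"tenure_cv must be >= 0, got {self.tenure_cv}")
        if not -1 < self.corr < 1:
            raise ValueError(f"corr must be in (-1, 1), got {self.corr}")

    @property
    def tenure_sd(self) -> float:
        """Implied SD of tenure, days."""
        return self.tenure_cv * self.tenure_mean

    @property
    def departure_sd(self) -> float:
        """SD of the departure date arrival + tenure, days."""
        var = (
            self.a_sd ** 2
            + self.tenure_sd ** 2
            + 2.0 * self.corr * self.a_sd * self.tenure_sd
        )
        if var <= 0:  # unreachable for |corr| < 1 with a_sd > 0
            raise ValueError(f"departure variance not positive ({var})")
        return math.sqrt(var)


@dataclass(frozen=True)
class CensusCurve:
    """Cumulative arrival/departure and census values on a day grid."""

    days: np.ndarray
    arrivals_cum: np.ndarray
    departures_cum: np.ndarray
    census: np.ndarray


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def cumulative_arrival(t, p: YearParams):
    """Expected number of females arrived by day ``t``: N * Phi((t-a)/s)."""
    t = np.asarray(t, dtype=float)
    out = p.N * ndtr((t - p.a_mean) / p.a_sd)
    return out if out.ndim else float(out)


def cumulative_departure(t, p: YearParams):
    """Expected number departed by day ``t``.

    Departure = arrival + tenure is Gaussian with mean
    ``a_mean + tenure_mean`` and SD :attr:`YearParams.departure_sd`.
    """
    t = np.asarray(t, dtype=float)
    out = p.N * ndtr((t - p.a_mean - p.tenure_mean) / p.departure_sd)
    return out if out.ndim else float(out)


def census(t, p: YearParams):
    """Expected count on day ``t``: C(t) = A(t) - D(t)."""
    t = np.asarray(t, dtype=float)
    out = p.N * (
        ndtr((t - p.a_mean) / p.a_sd)
        - ndtr((t - p.a_mean - p.tenure_mean) / p.departure_sd)
    )
    return out if out.ndim else float(out)


def census_curve(grid, p: YearParams) -> CensusCurve:
    """Evaluate A, D and C on a strictly increasing day grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a nonempty 1-D array of season days")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    a = cumulative_arrival(grid, p)
    d = cumulative_departure(grid, p)
    return CensusCurve(days=grid, arrivals_cum=a, departures_cum=d, census=a - d)


def peak_date(p: YearParams, resolution: float = 0.01, refine: bool = True) -> float:
    """Day on which the census curve attains its maximum.

    Grid search at ``resolution`` over [1, 120] (ties broken toward the
    earliest day), optionally refined by bounded scalar minimization within
    the winning grid cell.  The curve is unimodal for all valid parameters,
    so the refinement converges to the global maximum.
    """
    # coarse pass to bracket the mode, then a fine grid at `resolution`
    coarse = np.arange(SEASON_START, SEASON_END + 0.5, 0.5)
    t0 = coarse[int(np.argmax(census(coarse, p)))]
    lo = max(SEASON_START, t0 - 1.0)
    hi = min(SEASON_END, t0 + 1.0)
    fine = np.arange(lo, hi + resolution / 2, resolution)
    t1 = fine[int(np.argmax(census(fine, p)))]
    if not refine:
        return float(t1)
    res = minimize_scalar(
        lambda t: -census(t, p),
        bounds=(max(SEASON_START, t1 - resolution), min(SEASON_END, t1 + resolution)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x)


def correction_factor(t, p: YearParams, guard: float = CORRECTION_GUARD) -> float:
    """Multiplier m(t) = N / C(t) converting a day-``t`` count into N.

    Refuses days outside the usable census window: when C(t) < guard * N
    (multiplier above 1/guard) the estimate would be dominated by the tails
    of the fitted curves and :class:`OutsideCensusWindowError` is raised.
    """
    c = census(float(t), p)
    if c < guard * p.N:
        raise OutsideCensusWindowError(
            f"census on day {t} is {c:.3g}, below {guard:.0%} of N={p.N:.3g}: "
            "outside usable census window"
        )
    return p.N / c
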