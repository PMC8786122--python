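# Methods

## The model

The package estimates the *superpopulation* of a seasonal breeding
aggregation — the total number of distinct individuals that use a site over
one season — from sparse single-day counts. In asynchronous breeders
(northern elephant seal females are the motivating case) no single count
ever captures the whole population: arrivals spread over weeks and each
female stays only about a month.

For one site-season, arrival dates are Gaussian, `arrival ~ N(â, s²)`, and
each individual's tenure is Gaussian with mean `d̂` and SD `v·d̂`, possibly
correlated with its arrival date (correlation `c`). We take (arrival,
tenure) to be jointly bivariate Gaussian; this is the minimal assumption
under which both cumulative curves are closed-form Gaussian CDFs, because
departure = arrival + tenure is then itself Gaussian:

    A(t) = N·Φ((t − â)/s)
    D(t) = N·Φ((t − â − d̂)/σ_D),   σ_D² = s² + (v·d̂)² + 2·c·s·v·d̂
    C(t) = A(t) − D(t)

`C(t)` is the expected count on day `t`; `N` is the superpopulation. The
correction factor `m(t) = N / C(t)` converts a day-`t` count into an
estimate of `N`.

Tenure is *not* truncated at zero. The Gaussian tail admits negative
tenures with mass `Φ(−1/v)` (≈1e−16 at the default CV of 0.1212), so
`C(t)` may dip below zero by at most `N·Φ(−1/v)`; we keep the untruncated
closed form so that the individual-based simulator and the closed form
agree exactly in distribution. Property tests bound the dip by exactly this
mass.

**Day convention.** Day 1 is 1 December of the calendar year preceding the
season label; a season is labelled by the year of its January (season 2018
runs Dec 2017–Mar 2018; 14 Jan = day 45). An individual is counted on day
`t` iff `arrival ≤ t < arrival + tenure` (continuous time), so a 31-day
tenure occupies 31 census days. All curves are evaluated on days 1–120.

## Hierarchical multi-year fit

All seasons at one site are fitted jointly with season as a random effect.
Per season: `N_i, â_i, s_i, c_i, d̂_i, v_i`. The five timing parameters are
tied across seasons:

* `â_i ~ N(μ_a, σ_a²)`, `s_i ~ N(μ_s, σ_s²)`, `c_i ~ N(μ_c, σ_c²)` with
  the hyper-parameters estimated from the data;
* `d̂_i ~ N(31.06, 0.27²)` and `v_i ~ N(0.1212, 0.0062²)` — narrow priors
  fixed in advance (counts alone cannot separate tenure length from
  population size, so tenure must come from prior behavioral knowledge);
  we read these as per-season prior SDs, not across-year hyper-SDs;
* `N_i` is unconstrained (flat on (0, 1e7)) — no year-to-year consistency
  is assumed for population size.

A Y-season model therefore has 6Y + 10 parameters, 4 of them fixed.

**Likelihood.** Counts are Poisson around the curve,
`count(t) ~ Poisson(C(t))`, chosen because it is parameter-free and
respects count support; a Gaussian-CV alternative (`sd = cv·C(t)`) is
available via `FitConfig(noise="gaussian_cv")`. The attendance process
itself adds binomial-scale dispersion the Poisson model absorbs in
practice.

**Priors on hypers** (the model is insensitive to these at realistic data
sizes): flat `μ_a`, `μ_s` over wide bounds, flat `μ_c` on (−1, 1);
half-Gaussian(scale 10 d) on `σ_a`, `σ_s`; half-Gaussian(scale 0.5) on
`σ_c`.

**Sampler.** Adaptive Metropolis-within-Gibbs: each season's six
parameters are a block updated component-wise; one hyper block updates the
six estimated hyper-parameters (the hyper conditional involves no data
likelihood, only the year-level Gaussians). Correlations are proposed on
the Fisher-z scale with the tanh Jacobian in the target, keeping proposals
inside (−1, 1). Proposal scales adapt every 50 iterations during burn-in
toward 20–40% acceptance and are frozen afterwards, so the kept draws come
from a fixed kernel. Defaults: 4 chains × 20 000 iterations, 50% burn-in,
thin 10. Starting points are moment-based (count-weighted mean day minus
half the prior tenure; weighted day variance minus `d̂²/12` for the arrival
SD) and jittered per chain.

**Convergence** is diagnosed with rank-normalized split-R̂ (arviz) on every
sampled parameter; R̂ ≥ 1.05 anywhere sets `converged=False`, logs a
warning and is recorded in the output sidecar — never auto-rerun, never
silent. Sparse seasons legitimately mix slowly in their weakly identified
parameters (e.g. the arrival SD of a 3-count season); the flag makes that
visible.

**Timing statistics.** The peak census date is computed per posterior draw
by maximizing that draw's curve (coarse 0.25-day bracket, then a 0.01-day
local grid, vectorized across draws), then summarized, so its credible
interval propagates the joint posterior. Non-overlapping 95% intervals are
the criterion for a meaningful difference; intervals sharing an endpoint
count as overlapping (conservative).

**Peak search** elsewhere uses the same grid at 0.01-day resolution with
ties broken toward the earlier day, plus a bounded golden-section
refinement within the winning cell; the curve is unimodal so this attains
the analytic optimum (the fixed-tenure limit `â + d̂/2` is reproduced to
better than 1e−6 days).

## Correction tables

To be usable in future seasons a table must carry both year-to-year timing
variation and within-year posterior uncertainty. `correction_curve`
resamples fitted seasons *with replacement* (default 30 — matching how 30
year-samples can be drawn from a shorter series; when fewer seasons exist
they simply recur) and takes 40 joint posterior draws of the five timing
parameters within each, giving 1200 simulated curves with the population
pinned at a reference `N = 1000` (which cancels in the multiplier). Table
rows are the empirical mean and 2.5/97.5% quantiles of the 1200 multipliers
per day, pooled — no smoothing, no nesting of the two variance components.

**Domain guard.** A simulation contributes nothing on days where its
`C(t) < 5%·N` (multiplier > 20); a day where more than half the
simulations are guarded is marked unusable and reported as such rather
than given a fabricated band. `apply_correction` refuses unusable days and
names the nearest usable window. The 5% threshold reflects how quickly the
bands widen beyond ±5 days of the peak.

The default table window is 1 Jan–28 Feb (days 32–90), keyed by calendar
date on a non-leap calendar; `optimal_window` returns the contiguous run of
days whose 95% band width is within 1.1× the minimum — the recommended
counting window.

## The synthetic colony

The simulator realizes exactly the process the model assumes: season
parameters drawn from the hyper-distributions, individual (arrival, tenure)
pairs from the bivariate Gaussian (untruncated, cohort size `round(N)`),
presence by the half-open day rule, surveys on an irregular random subset
of days 10–110 with Poisson count noise by default. Default hyper values
describe a realistic colony: mean arrival day 45 (14 Jan) with a 1.85-day
between-year SD, 10-day within-year arrival spread (SD of that spread 1 d
across years), weak arrival-tenure correlation (0 ± 0.2), and the fixed
tenure priors above. Default season populations are uniform on 500–2000.

Because the simulator and the closed form share their distributional
assumptions, the simulator is a genuine brute-force oracle — at 1e5
individuals the empirical attendance matches `C(t)` within 2% of `N` in
sup-norm — but passing tests on it says nothing about features real
colonies have and the model lacks: storm-driven temporary emigration,
observer error structure beyond Poisson, mid-season recounts of the same
female at two sites, or drift in tenure behavior.

## Problem sizes and numerical choices

Tests fit reduced chains (2 × 10 000 iterations for the six-season
recovery check, smaller for unit tests); these recover simulated
populations to a few percent and keep the whole suite fast. `C(t)` is
floored at 1e−12 inside the Poisson log-likelihood; invalid proposals
(non-positive SDs, |c| ≥ 1, negative tenure) are rejected moves, not
errors. All randomness flows from explicit seeds (`numpy`
`default_rng`/`SeedSequence`); identical seed and config give bit-identical
chains and tables.

## Known limitations

* One site at a time; no colony-level random effect across sites.
* The count-error model is an assumption, not estimated; overdispersed
  counts would widen true uncertainty beyond the reported intervals.
* Correction tables extrapolate only to seasons exchangeable with the
  fitted ones — a colony whose phenology shifts needs refitting.
* Tenure priors encode one species' female attendance; applying the tool
  to another species requires its own tenure prior.
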