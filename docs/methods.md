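# Methods

This note documents the statistical model, the default parameters and the
numerical choices behind `poptrend`, and what the synthetic-data tests do
and do not demonstrate.

## The model

The unit of analysis is a count series: all censuses of one species at one
site, at dates `t_1 < … < t_K` (fractional years allowed; a month m is
encoded as `year + (m − 0.5)/12`). A series must hold at least 4 counts —
shorter series cannot support trend inference and are rejected (the
minimum can be raised, not lowered).

Latent states are the abundances `N_i` at the K distinct dates and annual
relative growth rates `r_i` on the K−1 intervals, with
`ln N_{i+1} = ln N_i + r_i Δt_i`. We model *r* rather than log-abundance
because *r* directly measures current dynamics: it is the natural place to
encode both smoothness (conditions in neighbouring years resemble each
other) and the demographic ceiling of the species.

Priors:

* `r_1 ~ N(0, 1)` — deliberately vague, centred on "no change";
* `r_{i+1} ~ N(r_i, 1/τ)` — the smoothing random walk. τ is the
  *smoothing precision*, default 100 (step sd 0.1/yr). Lowering τ produces
  a rougher rate sequence; τ = 1 effectively unlinks the intervals.
* optional upper truncation `r_i ≤ r_max`. Declines are never truncated.
* `N_1 ~ Uniform(C_1/2, 2 C_1)`, where `C_1` is the precision-weighted
  mean of the counts at `t_1`.

Observation model: each count `C_j` at date i contributes
`C_j ~ N(N_i, σ_j²)` with `σ_j = (C_max,j − C_min,j)/3.93` from its
standardized 95% interval. Several counts at the same date share one
latent state and contribute separate likelihood terms. The divisor is kept
at the conventional 3.93 (not 2·1.959964) to match standard practice for
this method.

### Unequal intervals

The smoothing step links consecutive *rates* with precision τ regardless
of the interval length, and each `r_i` is an *annual* rate applied over
`Δt_i` (log-linear growth within an interval). This keeps rates comparable
across intervals and makes the cap meaningful in annual units: with
`r_max = 0.299`, a 4-year gap bounds growth at `e^{4·0.299} ≈ 3.31`. An
alternative where the step variance grows with the gap
(`var = Δt_i/τ`, a true random walk in time) is available as
`dt_scaled_smoothing=True` but is off by default, matching the fixed-link
formulation of the method.

### The demographic cap

`r_max` is the species' maximum annual relative growth rate: tabulated
literature values where a demographic analysis exists, otherwise the
allometric relation `r_max = 1.375 W^{−0.315}` on adult female body mass W
(kg). The packaged table carries both kinds, flagged by `r_max_source`;
user values always win. One packaged value deserves a flag: the impala
entry is the published 0.401, although the allometry at the tabulated
W = 55 kg gives 0.389 (0.401 corresponds to W ≈ 50 kg). We ship the
published number as a table value and surface the discrepancy here rather
than "fixing" it. The blue wildebeest entry (0.247) similarly sits one
unit in the third decimal below the allometry at the tabulated mass
(0.2479 at W = 230) and is likewise flagged as a table value.

The truncation is implemented as an upper-truncated normal prior on each
`r_i` (including the normalizing term, which depends on `r_{i-1}`), the
distributionally clean equivalent of redrawing/clamping values above the
cap inside a Gibbs sampler. The cap should be disabled when immigration is
plausible — observed growth can then legitimately exceed the demographic
potential.

## Precision standardization

Rules, in order: a supplied 95% CI is used verbatim (even if asymmetric
around the count — the likelihood is still centred on the latent N with
the single derived σ); se/variance/cv go through `count ± 1.96·se`;
precision-free totals get `[0.95C, 1.20C]` (undercounting is far more
likely than double-counting, hence the asymmetry), guesstimates
`[0.80C, 1.20C]`. A sample count with no precision measure has no
published default; we apply a configurable ±100% relative interval with a
prominent warning — wider than a guesstimate's, since an unsampled-precision
partial count gives even less ground for confidence. Negative lower
bounds become 0.01; a zero count gets `[0, 0.01]`. Degenerate intervals
receive a σ floor of `0.01/3.93` so the likelihood never collapses.

## Aerial/ground conversion

The conversion factor *f* multiplies an aerial count to give its
ground-count equivalent, assumed to depend on the species class only
(five classes by size and coat colour). Harmonization rescales count and
interval bounds by *f* (or 1/*f*) and re-derives σ; the standardized count
tracks the scale its values are currently in, separately from the platform
that made the count, so harmonization is exactly invertible.
`target='auto'` resolves to the species' preferred platform (aerial for
elephant, dark species and giraffe; ground for light/brown species —
user-overridable), falling back to the series' majority method.

Estimation from parallel pairs (ground and aerial counts at most a month
apart): per pair a latent true ground-scale abundance `μ_j` with
`ground_j ~ N(μ_j, σ_G²)` and `aerial_j ~ N(μ_j/f, σ_A²)`, σ from the
standardized intervals — this is what "weighting by precision" means here.
Priors: `f ~ Lognormal(0, 1.5²)` (median 1, broad enough to cover the
published range 0.56–6.75) and `μ_j ~ Uniform(0, 10·max(ground_j,
aerial_j))`. Pairs are pooled within a class across sites; no site
effects. The model is validated by parameter recovery on simulated pairs
(the published factors were estimated from restricted-access data).

## Sampling and diagnostics

Both posteriors are low-dimensional (K ≤ a few dozen for trends; n+1 for
pairs), so a single-site random-walk Metropolis sampler with per-coordinate
proposal scales adapted during burn-in (diminishing adaptation toward 44%
acceptance; adaptation frozen afterwards) is simple and adequate. Defaults:
3 chains, 20,000 iterations, 10,000 burn-in, thin 5. Chains are seeded
independently from the user seed (SeedSequence-derived), so fits are
bit-reproducible given a seed. Split-R̂ and ESS are computed with arviz
over the latent log-abundances, the rates, and the mean rate; a trend fit
whose worst R̂ exceeds 1.1 is returned but flagged and warned about, while
the conversion fit raises, since a scalar factor that fails to converge
has no usable summary. Chain initialization is empirical (log of the
precision-weighted counts, observed log-slopes clipped inside the
support). `exp()` overflow is guarded by rejecting states with
`ln N > 50`.

## Derived quantities

* Mean growth rate over the period: per draw, the Δt-weighted mean of the
  `r_i`, which telescopes to `(ln N_K − ln N_1)/(t_K − t_1)`. Its
  posterior summarizes the overall trend; the per-interval rates show
  periods deviating from it.
* Trajectory between census dates: per draw, log-linear within the
  containing interval; quantiles over draws give the credible band. No
  extrapolation outside `[t_1, t_K]`.

A structural consequence worth knowing: because each draw is log-linear
inside an interval, the mid-gap log-abundance is the average of the
endpoint values, so the band inside a gap is governed by the endpoint
uncertainty — with well-pinned endpoints the band can even be narrowest
mid-gap (the regression-at-the-centre effect). "Precision is better where
counts are numerous" holds in the sense that densely and precisely counted
dates have tighter bands than gaps flanked by vague counts.

## The synthetic-data generator

`simulate_series` draws counts around a piecewise-exponential truth
`N(t) = N0·exp(∫r)`, with per-date platform and statistical method, aerial
expectations biased by a true conversion factor (`N/f`), normal noise
(sd = cv·expectation, floored at zero) and precision reported per regime
(ci95/se/cv/none). An optional lognormal noise mode exists for
misspecification checks. `simulate_pairs` draws latent abundances
lognormally (median 500, log-sd 0.5) and observes both platforms with
cv-proportional noise and exact 95% CIs.

What it emulates: method heterogeneity, irregular dates, known truth.
What it does not: overdispersion beyond the stated CI, correlated errors
between censuses, detection trends over time, site effects in conversion,
density dependence. Passing recovery tests therefore demonstrates the
estimator is calibrated *under its own assumptions* (CI-consistent,
independent noise), not that real census errors are this well behaved.

Default test conditions: trend recovery uses 100 series of 15 counts over
30 years at 10% CV with exact CIs and two-segment truths drawn from
U(−0.15, 0.15); conversion recovery uses 40 pairs per replicate at 10% CV
with true factors spanning the published range (0.5, 2.3, 6.7). Sampler
sizes in tests are scaled to a few thousand post-burn-in draws, which the
R̂/ESS diagnostics show is ample for these posteriors.

## Known limitations

* No covariates on *r*, no density dependence, no time-varying smoothing
  precision — deliberate non-goals.
* The normal observation model admits (and must floor) negative-count
  mass for very vague intervals; counts are treated as reals throughout.
* Conversion factors are class-level constants; habitat- or site-specific
  detectability differences fold into them silently.
* Species in the packaged class table without published mass or r_max
  (e.g. sable) require user-supplied values before the cap can be used.
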