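# poptrend

Population trajectories and relative growth rates from heterogeneous
wildlife count series.

Long-running census archives — the kind protected-area managers actually
have — mix aerial and ground platforms, total counts, sample estimates and
expert guesstimates, reported with anything from a full confidence interval
to no precision at all, at irregular and sometimes fractional-year dates.
`poptrend` turns such a series into a defensible population trend in three
steps:

1. **Standardize precision.** Every count is given a 95% interval: supplied
   CIs are used as-is; standard errors, variances and CVs are converted via
   `count ± 1.96·se`; precision-free total counts get the asymmetric
   `[0.95C, 1.20C]` (a total count is nearly a lower bound), guesstimates
   `[0.80C, 1.20C]`. Negative bounds are floored at 0.01 and a zero count
   (local extinction) gets `[0, 0.01]`. The observation sd is
   `σ = (C_max − C_min)/3.93`.
2. **Harmonize platforms.** Aerial and ground counts disagree
   systematically with body size and coat colour. A class-level factor *f*
   (aerial → ground; packaged values for five species classes, from
   medium light/brown *f* = 6.747 down to elephant *f* = 0.659) rescales a
   mixed series into one platform's scale. *f* can be (re-)estimated from
   parallel count pairs with a precision-weighted Bayesian model.
3. **Fit the trend.** A Bayesian state-space model with latent abundances
   `N_i` at the K census dates and annual relative growth rates
   `r_i = ln(N_{i+1}/N_i)/Δt_i` on the K−1 intervals:

   ```
   ln N_{i+1} = ln N_i + r_i Δt_i
   r_1 ~ N(0, 1),   r_{i+1} ~ N(r_i, 1/τ)        (smoothing, default τ = 100)
   r_i ≤ r_max                                    (demographic cap, optional)
   N_1 ~ Uniform(C_1/2, 2 C_1)
   C_j ~ N(N_i, σ_j²)                             (precision-weighted likelihood)
   ```

   `r_max` is the species' maximum annual growth rate, tabulated or from
   the body-mass allometry `r_max = 1.375 W^(−0.315)` (adult female mass W
   in kg). Posterior sampling is an adaptive Metropolis-within-Gibbs
   sampler (numba-accelerated, seed-reproducible) with split-R̂/ESS
   diagnostics via arviz.

Intended users: wildlife ecologists and protected-area analysts who need
trends and growth rates from messy historical count data, not just from
standardized modern surveys.

## Worked example

`examples/03_fit_trend.py` simulates a population growing at 0.06/yr then
collapsing at −0.10/yr, censused 16 times over 28 years with 12% noise, and
fits the trend model:

```
  date  N_median  N_low95  N_high95
1982.0    1093.9    863.4    1345.1
1983.9    1358.5   1131.0    1589.0
...
2008.1     806.0    679.8     944.7
2010.0     812.8    654.8     966.6

mean r over 1982-2010: -0.0107 [-0.0213, -0.0000]
true mean r:           -0.0200
convergence: max split-R-hat = 1.009, min ESS = 309
```

Each row is the posterior median and 95% credible band of abundance at a
census date; `mean r` is the Δt-weighted mean annual growth rate over the
whole period — its negative CrI says the late collapse outweighs the early
growth. The other examples cover precision standardization (`01`),
aerial/ground harmonization (`02`), conversion-factor estimation from
parallel pairs (`04`), and the effect of the smoothing precision τ and the
r_max cap (`05`).

The same workflow is available from the shell:

```sh
poptrend simulate -o sim --rates 0.05 --seed 7
poptrend prepare sim/counts.csv -o prep
poptrend fit prep/prepared_*.csv -o fit --seed 3
poptrend calibrate pairs.csv -o cal
```

`prepare` writes standardized, harmonized per-series CSVs plus a report of
applied rules and rejected series (fewer than 4 counts); `fit` writes
trajectory/rate CSVs, a summary JSON and Figure-style plots; every command
writes a manifest sufficient to reproduce its outputs exactly.

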