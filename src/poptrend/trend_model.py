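"""Bayesian state-space trend model for standardized count series.

The latent states are the abundances ``N_i`` at the K distinct count dates
``t_1 < ... < t_K`` and the annual relative growth rates ``r_i`` on the
K-1 intervals between them:

    ln N_{i+1} = ln N_i + r_i * dt_i,            dt_i = t_{i+1} - t_i (years)

Priors encode three pieces of ecology:

* smoothness — neighbouring years resemble each other, so consecutive rates
  are linked by a normal random step, ``r_{i+1} ~ N(r_i, 1/tau)`` with
  smoothing precision ``tau`` (default 100, i.e. sd 0.1); ``r_1 ~ N(0, 1)``;
* demographic ceiling — when ``use_rmax`` is on, every rate is upper-
  truncated at the species' maximum annual growth rate ``r_max`` (declines
  stay unbounded; omit the cap if immigration is suspected);
* a weakly informative anchor on the first abundance,
  ``N_1 ~ Uniform(C_1/2, 2*C_1)`` with ``C_1`` the (precision-weighted)
  first count.

Each observation ``C_j`` at date i enters as ``C_j ~ N(N_i, sigma_j^2)``
with sigma derived from its standardized 95% interval, so precise counts
pull the trajectory harder than vague ones.  Posterior sampling uses the
package's adaptive Metropolis-within-Gibbs kernel over
``(ln N_1, r_1, ..., r_{K-1})`` with multiple independently seeded chains;
split-R-hat and effective sample sizes are computed with arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ExtrapolationError,
    InvalidArgumentError,
    ModelError,
)
from .precision import StandardizedSeries

__all__ = [
    "TrendModelConfig",
    "TrendModel",
    "TrendFit",
    "build_model",
    "fit_trend",
    "mean_growth_rate",
    "trajectory_at",
]

#: dates closer than this (in years) are treated as the same census date
_DATE_ATOL = 1e-9


@dataclass(frozen=True)
class TrendModelConfig:
    """Sampler and prior settings for one trend fit.

    ``smoothing_precision`` is the reciprocal variance tau of the random-walk
    step between consecutive rates (default 100 = sd 0.1; lower it for a
    rougher trajectory).  ``dt_scaled_smoothing`` optionally lets the step
    variance grow with the interval length (variance dt/tau) instead of the
    default fixed 1/tau link.
    """

    smoothing_precision: float = 100.0
    use_rmax: bool = True
    r_max: float | None = None
    dt_scaled_smoothing: bool = False
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if not self.smoothing_precision > 0:
            raise InvalidArgumentError("smoothing_precision must be > 0")
        if self.chains < 2:
            raise InvalidArgumentError("need >= 2 chains for diagnostics")
        if not (self.iterations > self.burn_in >= 0):
            raise InvalidArgumentError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise InvalidArgumentError("thin must be >= 1")
        if self.use_rmax and self.r_max is not None and not self.r_max > 0:
            raise InvalidArgumentError("r_max must be > 0")
        if self.use_rmax and self.r_max is None:
            raise InvalidArgumentError(
                "use_rmax is on but no r_max given; pass r_max "
                "(e.g. from reference_data.get_rmax) or set use_rmax=False"
            )


@dataclass(frozen=True)
class TrendModel:
    """Assembled data and priors for one series, ready to sample."""

    site: str
    species: str
    dates: np.ndarray          # (K,) distinct census dates
    dt: np.ndarray             # (K-1,) interval lengths in years
    obs_date_index: np.ndarray  # (n_obs,) index into dates per observation
    obs_count: np.ndarray      # (n_obs,)
    obs_sigma: np.ndarray      # (n_obs,)
    first_count: float         # precision-weighted count at t_1 (anchors N_1)
    config: TrendModelConfig

    @property
    def n_states(self) -> int:
        return len(self.dates)

    @property
    def n_rates(self) -> int:
        return len(self.dates) - 1


def build_model(series: StandardizedSeries,
                config: TrendModelConfig) -> TrendModel:
    """Assemble the state-space model from a standardized (and, if needed,
    method-harmonized) series.

    Counts sharing a date contribute separate likelihood terms for one
    shared latent abundance; their precision-weighted mean anchors the
    ``N_1`` prior when they fall on the first date.
    """
    if not isinstance(series, StandardizedSeries):
        raise InvalidArgumentError(
            "build_model needs a StandardizedSeries (run precision."
            "standardize_series, and conversion.harmonize_series for "
            "mixed-method data, first)"
        )
    obs_dates = np.array([c.date for c in series.counts], dtype=float)
    obs_count = np.array([c.count for c in series.counts], dtype=float)
    obs_sigma = np.array([c.sigma for c in series.counts], dtype=float)
    if np.any(obs_sigma <= 0):
        raise InvalidArgumentError("every observation needs sigma > 0")

    order = np.argsort(obs_dates, kind="stable")
    obs_dates, obs_count, obs_sigma = (
        obs_dates[order], obs_count[order], obs_sigma[order])
    # collapse dates closer than _DATE_ATOL onto shared latent states
    dates = [obs_dates[0]]
    idx = np.zeros(len(obs_dates), dtype=np.int64)
    for j in range(1, len(obs_dates)):
        if obs_dates[j] - dates[-1] > _DATE_ATOL:
            dates.append(obs_dates[j])
        idx[j] = len(dates) - 1
    dates = np.asarray(dates)
    if len(dates) < 2:
        raise ModelError(
            f"series {series.site}/{series.species}: need at least two "
            f"distinct census dates to estimate a trend"
        )
    first = idx == 0
    w = 1.0 / obs_sigma[first] ** 2
    c1 = float(np.sum(w * obs_count[first]) / np.sum(w))
    if not c1 > 0:
        # extinct-at-start series: anchor on the interval floor instead
        c1 = max(c1, 0.005)
    return TrendModel(
        site=series.site, species=series.species,
        dates=dates, dt=np.diff(dates),
        obs_date_index=idx, obs_count=obs_count, obs_sigma=obs_sigma,
        first_count=c1, config=config,
    )


@dataclass(frozen=True)
class TrendFit:
    """Posterior draws and summaries for one fitted series.

    ``n_draws`` has shape (chains, kept, K) on the abundance scale,
    ``r_draws`` shape (chains, kept, K-1) in per-year units.
    """

    model: TrendModel
    n_draws: np.ndarray
    r_draws: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def dates(self) -> np.ndarray:
        return self.model.dates

    @property
    def config(self) -> TrendModelConfig:
        return self.model.config

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("max_rhat", np.inf)
                    <= self.config.rhat_threshold)

    @property
    def n_flat(self) -> np.ndarray:
        """(total draws, K) abundance draws pooled across chains."""
        return self.n_draws.reshape(-1, self.n_draws.shape[-1])

    @property
    def r_flat(self) -> np.ndarray:
        """(total draws, K-1) rate draws pooled across chains."""
        return self.r_draws.reshape(-1, self.r_draws.shape[-1])

    def trajectory_summary(self) -> pd.DataFrame:
        """Per-date posterior median and 95% credible band of N."""
        q = np.quantile(self.n_flat, [0.5, 0.025, 0.975], axis=0)
        return pd.DataFrame({
            "date": self.dates,
            "N_median": q[0], "N_low95": q[1], "N_high95": q[2],
        })

    def rates_summary(self) -> pd.DataFrame:
        """Per-interval posterior mean and 95% CrI of the annual rate r."""
        r = self.r_flat
        lo, hi = np.quantile(r, [0.025, 0.975], axis=0)
        return pd.DataFrame({
            "interval_start": self.dates[:-1],
            "interval_end": self.dates[1:],
            "r_mean": r.mean(axis=0), "r_low95": lo, "r_high95": hi,
        })


def _initial_theta(model: TrendModel, rng: np.random.Generator) -> np.ndarray:
    """Empirical starting point (log first count + observed log-slopes),
    jittered per chain and forced inside the prior support."""
    cfg = model.config
    K = model.n_states
    # weighted mean observed count per date, floored away from zero
    wm = np.empty(K)
    for i in range(K):
        sel = model.obs_date_index == i
        w = 1.0 / model.obs_sigma[sel] ** 2
        wm[i] = max(np.sum(w * model.obs_count[sel]) / np.sum(w), 1e-2)
    lo, hi = np.log(model.first_count / 2), np.log(2 * model.first_count)
    ln_n1 = np.clip(np.log(wm[0]) + rng.uniform(-0.05, 0.05),
                    lo + 1e-6, hi - 1e-6)
    r = np.diff(np.log(wm)) / model.dt
    r = np.clip(r + rng.normal(0, 0.02, size=K - 1), -3.0, 3.0)
    if cfg.use_rmax:
        r = np.minimum(r, cfg.r_max - 1e-6)
    return np.concatenate([[ln_n1], r])


def fit_trend(series_or_model, config: TrendModelConfig | None = None,
              **config_overrides) -> TrendFit:
    """Sample the posterior of the trend model.

    Accepts either a :class:`StandardizedSeries` (plus a config) or an
    already-built :class:`TrendModel`.  Runs ``config.chains`` independently
    seeded chains, discards burn-in, thins, and attaches split-R-hat / ESS
    diagnostics.  A fit whose worst R-hat exceeds ``rhat_threshold`` is
    still returned but flagged (``converged`` False) with a warning.
    """
    from . import _samplers

    if isinstance(series_or_model, TrendModel):
        model = series_or_model
        if config is not None or config_overrides:
            cfg = replace(config or model.config, **config_overrides)
            model = replace(model, config=cfg)
    else:
        if config is None:
            config = TrendModelConfig(**config_overrides)
        elif config_overrides:
            config = replace(config, **config_overrides)
        model = build_model(series_or_model, config)
    cfg = model.config

    rmax = cfg.r_max if cfg.use_rmax else 0.0
    seeds = _samplers.chain_seeds(cfg.seed, cfg.chains)
    rng_master = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(1)[0])
    chains = []
    for s in seeds:
        theta0 = _initial_theta(model, rng_master)
        draws = _samplers.run_trend_chain(
            theta0, cfg.iterations, cfg.burn_in, cfg.thin, s,
            model.dt, model.obs_date_index,
            model.obs_count, model.obs_sigma,
            cfg.smoothing_precision, rmax, cfg.use_rmax,
            cfg.dt_scaled_smoothing,
            np.log(model.first_count / 2), np.log(2 * model.first_count),
        )
        chains.append(draws)
    theta = np.stack(chains)                      # (chains, kept, K)
    ln_n1 = theta[:, :, 0]
    r = theta[:, :, 1:]
    # reconstruct the latent log-abundance path per draw
    ln_n = np.empty(theta.shape)
    ln_n[:, :, 0] = ln_n1
    ln_n[:, :, 1:] = ln_n1[:, :, None] + np.cumsum(r * model.dt, axis=-1)
    fit = TrendFit(model=model, n_draws=np.exp(ln_n), r_draws=r,
                   diagnostics=_diagnostics(ln_n, r, model.dt))
    if not fit.converged:
        warnings.warn(
            f"trend fit {model.site}/{model.species}: max split-R-hat "
            f"{fit.diagnostics['max_rhat']:.3f} exceeds "
            f"{cfg.rhat_threshold}; inspect diagnostics / raise iterations",
            stacklevel=2,
        )
    return fit


def _diagnostics(ln_n: np.ndarray, r: np.ndarray, dt: np.ndarray) -> dict:
    import arviz as az

    span = dt.sum()
    mean_r = (ln_n[:, :, -1] - ln_n[:, :, 0]) / span
    ds = az.convert_to_dataset(
        {"log_N": ln_n, "r": r, "mean_r": mean_r[:, :, None]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    per_param = {
        "log_N": np.asarray(rhat["log_N"]),
        "r": np.asarray(rhat["r"]),
        "mean_r": float(np.asarray(rhat["mean_r"]).max()),
    }
    all_rhat = np.concatenate([per_param["log_N"], per_param["r"],
                               [per_param["mean_r"]]])
    all_ess = np.concatenate([np.asarray(ess["log_N"]).ravel(),
                              np.asarray(ess["r"]).ravel(),
                              np.asarray(ess["mean_r"]).ravel()])
    return {
        "rhat": per_param,
        "max_rhat": float(np.nanmax(all_rhat)),
        "min_ess": float(np.nanmin(all_ess)),
    }


def mean_growth_rate(fit: TrendFit) -> dict:
    """Posterior of the mean annual growth rate over the whole period.

    Per draw this is the dt-weighted mean of the interval rates, which
    telescopes to ``(ln N_K - ln N_1) / (t_K - t_1)``: the overall trend.
    Returns mean, 95% CrI and the pooled draws.
    """
    ln_n = np.log(fit.n_flat)
    span = fit.dates[-1] - fit.dates[0]
    draws = (ln_n[:, -1] - ln_n[:, 0]) / span
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"mean": float(draws.mean()), "low95": float(lo),
            "high95": float(hi), "samples": draws}


def trajectory_at(fit: TrendFit, query_dates) -> pd.DataFrame:
    """Posterior median and 95% band of N at arbitrary dates.

    Within each interval the trajectory is log-linear (piecewise
    exponential): ``ln N(t) = ln N_i + r_i (t - t_i)``.  Queries outside
    the fitted range raise — the model does not extrapolate.
    """
    q = np.atleast_1d(np.asarray(query_dates, dtype=float))
    t = fit.dates
    if np.any(q < t[0] - _DATE_ATOL) or np.any(q > t[-1] + _DATE_ATOL):
        raise ExtrapolationError(
            f"query dates must lie within [{t[0]}, {t[-1]}]"
        )
    idx = np.clip(np.searchsorted(t, q, side="right") - 1, 0, len(t) - 2)
    ln_n = np.log(fit.n_flat)            # (draws, K)
    r = fit.r_flat                       # (draws, K-1)
    ln_at = ln_n[:, idx] + r[:, idx] * (q - t[idx])[None, :]
    qs = np.quantile(np.exp(ln_at), [0.5, 0.025, 0.975], axis=0)
    return pd.DataFrame({
        "date": q, "N_median": qs[0], "N_low95": qs[1], "N_high95": qs[2],
    })
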