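"""Numba-jitted MCMC kernels.

Both posteriors in this package (the state-space trend model and the
conversion-factor model) are low-dimensional with cheap densities, so a
single-site random-walk Metropolis sampler with per-coordinate scales
adapted during burn-in (diminishing adaptation toward a 44% acceptance
rate) mixes well and runs in milliseconds.  Adaptation stops at the end of
burn-in, so the retained draws come from a fixed-kernel Markov chain.

Everything here works on plain float64 arrays; model assembly, seeding of
independent chains and convergence diagnostics live in the calling modules.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)

# guard against exp() overflow in the latent-abundance path
_MAX_LOG_N = 50.0


@njit(cache=False)
def _log_phi(x):
    """log of the standard normal CDF, stable for x >= -5 (we only need x >= 0)."""
    return math.log(0.5 * math.erfc(-x / _SQRT2))


@njit(cache=False)
def trend_log_post(theta, dt, obs_idx, obs_c, obs_sd,
                   tau, rmax, use_rmax, dt_scaled, ln_lo, ln_hi):
    """Unnormalized log posterior of the trend model.

    theta = (ln N_1, r_1, ..., r_{K-1}).  Priors: N_1 uniform on the count-
    anchored interval (hence the +ln N_1 Jacobian in log space); r_1 standard
    normal; r_{i+1} normal around r_i with precision tau, all rates upper-
    truncated at rmax when capping is on.  Observations are normal around
    the latent abundance at their date.
    """
    K = dt.shape[0] + 1
    ln_n1 = theta[0]
    if ln_n1 < ln_lo or ln_n1 > ln_hi:
        return -np.inf
    lp = ln_n1  # Jacobian: uniform prior on N_1, sampled in log space

    r_prev = theta[1]
    if use_rmax and r_prev > rmax:
        return -np.inf
    lp += -0.5 * r_prev * r_prev
    for i in range(2, K):
        r = theta[i]
        if use_rmax and r > rmax:
            return -np.inf
        if dt_scaled:
            var = dt[i - 1] / tau
        else:
            var = 1.0 / tau
        lp += -0.5 * (r - r_prev) * (r - r_prev) / var
        if use_rmax:
            # normalizer of the upper-truncated smoothing step depends on r_prev
            lp -= _log_phi((rmax - r_prev) / math.sqrt(var))
        r_prev = r

    # latent log-abundance path
    ln_n = np.empty(K)
    ln_n[0] = ln_n1
    for i in range(K - 1):
        ln_n[i + 1] = ln_n[i] + theta[1 + i] * dt[i]
        if ln_n[i + 1] > _MAX_LOG_N:
            return -np.inf

    for j in range(obs_c.shape[0]):
        n_i = math.exp(ln_n[obs_idx[j]])
        z = (obs_c[j] - n_i) / obs_sd[j]
        lp += -0.5 * z * z
    return lp


@njit(cache=False)
def run_trend_chain(theta0, n_iter, burn_in, thin, seed,
                    dt, obs_idx, obs_c, obs_sd,
                    tau, rmax, use_rmax, dt_scaled, ln_lo, ln_hi):
    """One adaptive single-site Metropolis chain for the trend model.

    Returns the kept draws with shape (n_kept, P) where
    n_kept = (n_iter - burn_in) // thin.
    """
    np.random.seed(seed)
    P = theta0.shape[0]
    theta = theta0.copy()
    log_scale = np.full(P, math.log(0.1))
    acc = np.zeros(P)
    n_kept = (n_iter - burn_in) // thin
    out = np.empty((n_kept, P))
    lp = trend_log_post(theta, dt, obs_idx, obs_c, obs_sd,
                        tau, rmax, use_rmax, dt_scaled, ln_lo, ln_hi)
    batch = 50
    kept = 0
    for it in range(n_iter):
        for p in range(P):
            old = theta[p]
            theta[p] = old + math.exp(log_scale[p]) * np.random.normal()
            lp_new = trend_log_post(theta, dt, obs_idx, obs_c, obs_sd,
                                    tau, rmax, use_rmax, dt_scaled,
                                    ln_lo, ln_hi)
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[p] += 1.0
            else:
                theta[p] = old
        if it < burn_in and (it + 1) % batch == 0:
            delta = min(0.2, 1.0 / math.sqrt((it + 1) / batch))
            for p in range(P):
                if acc[p] / batch > 0.44:
                    log_scale[p] += delta
                else:
                    log_scale[p] -= delta
                acc[p] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_kept:
            out[kept] = theta
            kept += 1
    return out


@njit(cache=False)
def pairs_log_post(theta, ground, aerial, sd_g, sd_a, mu_hi, prior_sd):
    """Unnormalized log posterior of the conversion-factor model.

    theta = (ln f, mu_1, ..., mu_n): f is the aerial-to-ground factor with a
    lognormal(0, prior_sd^2) prior; each latent true ground-scale abundance
    mu_j has a uniform prior on (0, mu_hi_j).  Likelihood: ground_j normal
    around mu_j, aerial_j normal around mu_j / f, with the sds derived from
    each count's standardized 95% interval (precision weighting).
    """
    x = theta[0]
    if abs(x) > 20.0:
        return -np.inf
    lp = -0.5 * (x / prior_sd) * (x / prior_sd)
    f = math.exp(x)
    for j in range(ground.shape[0]):
        mu = theta[1 + j]
        if mu <= 0.0 or mu >= mu_hi[j]:
            return -np.inf
        zg = (ground[j] - mu) / sd_g[j]
        za = (aerial[j] - mu / f) / sd_a[j]
        lp += -0.5 * zg * zg - 0.5 * za * za
    return lp


@njit(cache=False)
def run_pairs_chain(theta0, n_iter, burn_in, thin, seed,
                    ground, aerial, sd_g, sd_a, mu_hi, prior_sd):
    """One adaptive single-site Metropolis chain for the pairs model."""
    np.random.seed(seed)
    P = theta0.shape[0]
    theta = theta0.copy()
    log_scale = np.empty(P)
    log_scale[0] = math.log(0.1)
    for p in range(1, P):
        log_scale[p] = math.log(max(1e-3, 0.5 * sd_g[p - 1]))
    acc = np.zeros(P)
    n_kept = (n_iter - burn_in) // thin
    out = np.empty((n_kept, P))
    lp = pairs_log_post(theta, ground, aerial, sd_g, sd_a, mu_hi, prior_sd)
    batch = 50
    kept = 0
    for it in range(n_iter):
        for p in range(P):
            old = theta[p]
            theta[p] = old + math.exp(log_scale[p]) * np.random.normal()
            lp_new = pairs_log_post(theta, ground, aerial, sd_g, sd_a,
                                    mu_hi, prior_sd)
            if math.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                acc[p] += 1.0
            else:
                theta[p] = old
        if it < burn_in and (it + 1) % batch == 0:
            delta = min(0.2, 1.0 / math.sqrt((it + 1) / batch))
            for p in range(P):
                if acc[p] / batch > 0.44:
                    log_scale[p] += delta
                else:
                    log_scale[p] -= delta
                acc[p] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_kept:
            out[kept] = theta
            kept += 1
    return out


def chain_seeds(seed: int, n_chains: int) -> list[int]:
    """Independent 31-bit chain seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n_chains)]
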