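"""Harmonizing aerial and ground counts, and estimating conversion factors.

Aerial and ground censuses of the same population disagree systematically:
light-coloured species are undercounted from the air, large dark ones from
the ground.  A class-level multiplicative factor ``f`` (applied to an
aerial count to obtain its ground equivalent) renders the two comparable.
:func:`harmonize_series` rescales a standardized series into one method's
scale; :func:`fit_conversion_factors` estimates ``f`` per species class
from pairs of parallel (near-simultaneous) aerial and ground counts with a
Bayesian latent-abundance model that weights each count by its precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConvergenceError,
    InvalidArgumentError,
    MissingDataError,
)
from .precision import StandardizedCount, StandardizedSeries, ci_to_sigma
from .reference_data import (
    SPECIES_CLASSES,
    ConversionEntry,
    SpeciesProfile,
    get_conversion_factor,
)

__all__ = [
    "ParallelPair",
    "FactorPosterior",
    "McmcConfig",
    "harmonize_series",
    "fit_conversion_factors",
]

#: parallel counts must be at most a month apart
MAX_PAIR_GAP_YEARS = 1.0 / 12.0


@dataclass(frozen=True)
class ParallelPair:
    """One near-simultaneous ground/aerial count pair of a species class."""

    species_class: str
    site: str
    date: float
    ground: StandardizedCount
    aerial: StandardizedCount

    def __post_init__(self):
        if self.species_class not in SPECIES_CLASSES:
            raise InvalidArgumentError(
                f"unknown species class {self.species_class!r}"
            )
        gap = abs(self.ground.date - self.aerial.date)
        if gap > MAX_PAIR_GAP_YEARS + 1e-9:
            raise InvalidArgumentError(
                f"parallel counts must be within a month of each other "
                f"(gap {gap:.3f} years)"
            )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings for the conversion-factor model."""

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.1
    prior_log_sd: float = 1.5  # lognormal(0, 1.5^2) prior on f: median 1, broad

    def __post_init__(self):
        if self.chains < 2:
            raise InvalidArgumentError("need >= 2 chains for diagnostics")
        if not (self.iterations > self.burn_in >= 0):
            raise InvalidArgumentError("need iterations > burn_in >= 0")


@dataclass(frozen=True)
class FactorPosterior:
    """Posterior of the aerial-to-ground factor f for one species class."""

    species_class: str
    samples: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    diagnostics: dict

    def as_entry(self) -> ConversionEntry:
        """Summarize into the reference-table schema (mean + 95% CrI)."""
        return ConversionEntry(
            species_class=self.species_class, factor=self.mean,
            ci_low=self.ci_low, ci_high=self.ci_high,
        )


def _resolve_target(series: StandardizedSeries, profile: SpeciesProfile,
                    target: str) -> str:
    if target in ("aerial", "ground"):
        return target
    if target != "auto":
        raise InvalidArgumentError(
            f"target must be 'aerial', 'ground' or 'auto', got {target!r}"
        )
    if profile.preferred_field_method in ("aerial", "ground"):
        return profile.preferred_field_method
    methods = [c.scale for c in series.counts
               if c.scale in ("aerial", "ground")]
    if not methods:
        raise MissingDataError(
            f"series {series.site}/{series.species}: no field methods "
            f"recorded, cannot resolve target='auto'"
        )
    # majority method; ties resolve to ground (the reference scale of f)
    n_ground = sum(m == "ground" for m in methods)
    return "ground" if n_ground >= len(methods) - n_ground else "aerial"


def harmonize_series(series: StandardizedSeries, profile: SpeciesProfile,
                     target: str = "auto",
                     factors: dict[str, ConversionEntry] | None = None
                     ) -> StandardizedSeries:
    """Rescale every count of a standardized series into one method's scale.

    With factor ``f`` (aerial to ground) for the profile's species class:
    records already in the target scale pass through unchanged; aerial
    counts converted to ground scale are multiplied by ``f`` (count and both
    CI bounds), ground counts converted to aerial scale divided by ``f``.
    Sigma is re-derived from the transformed interval.  ``target='auto'``
    resolves to the profile's preferred field method, falling back to the
    majority method in the series.
    """
    entry = get_conversion_factor(profile.species_class, factors)
    f = entry.factor
    target = _resolve_target(series, profile, target)
    out = []
    for c in series.counts:
        current = c.scale
        if current == target:
            out.append(c)
            continue
        if current not in ("aerial", "ground"):
            raise MissingDataError(
                f"{series.site}/{series.species} @ {c.date}: record has no "
                f"field method but needs conversion to {target!r}"
            )
        scale = f if target == "ground" else 1.0 / f
        rec = replace(c.record, count=c.record.count * scale)
        lo, hi = c.ci_low * scale, c.ci_high * scale
        out.append(StandardizedCount(
            record=rec, ci_low=lo, ci_high=hi, sigma=ci_to_sigma(lo, hi),
            notes=c.notes + (
                f"converted {current} -> {target} (factor {scale:.6g})",),
            scale=target,
        ))
    return StandardizedSeries(site=series.site, species=series.species,
                              counts=tuple(out))


def fit_conversion_factors(pairs, mcmc: McmcConfig | None = None
                           ) -> dict[str, FactorPosterior]:
    """Estimate the aerial-to-ground factor per species class from parallel
    count pairs.

    Model, per class k with pairs j: a latent true ground-scale abundance
    ``mu_j`` with ``ground_j ~ N(mu_j, sigma_Gj^2)`` and
    ``aerial_j ~ N(mu_j / f_k, sigma_Aj^2)``; the sigmas come from each
    count's standardized interval, so precise pairs weigh more.  Priors:
    ``f_k`` lognormal with median 1 and broad log-sd, ``mu_j`` uniform on
    ``(0, 10 * max(ground_j, aerial_j))``.  Requires at least two pairs per
    class; raises :class:`ConvergenceError` if diagnostics fail.
    """
    from . import _samplers

    mcmc = mcmc or McmcConfig()
    by_class: dict[str, list[ParallelPair]] = {}
    for p in pairs:
        by_class.setdefault(p.species_class, []).append(p)
    result = {}
    for klass, ps in sorted(by_class.items()):
        if len(ps) < 2:
            raise InvalidArgumentError(
                f"class {klass!r}: need >= 2 parallel pairs, got {len(ps)}"
            )
        result[klass] = _fit_one_class(klass, ps, mcmc)
    return result


def _fit_one_class(klass, ps, mcmc) -> FactorPosterior:
    import arviz as az

    from . import _samplers

    g = np.array([p.ground.count for p in ps])
    a = np.array([p.aerial.count for p in ps])
    sg = np.array([p.ground.sigma for p in ps])
    sa = np.array([p.aerial.sigma for p in ps])
    mu_hi = 10.0 * np.maximum(g, a)
    mu_hi = np.maximum(mu_hi, 1.0)  # proper support even for zero pairs

    seeds = _samplers.chain_seeds(mcmc.seed, mcmc.chains)
    rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed).spawn(1)[0])
    # empirical start: f ~ ratio of totals, mu ~ ground counts
    x0 = float(np.log(max(g.sum(), 1e-3) / max(a.sum(), 1e-3)))
    chains = []
    for s in seeds:
        theta0 = np.concatenate(
            [[np.clip(x0 + rng.normal(0, 0.05), -19, 19)],
             np.clip(g + rng.normal(0, 0.02 * np.maximum(g, 1.0)),
                     1e-3, mu_hi * 0.999)])
        draws = _samplers.run_pairs_chain(
            theta0, mcmc.iterations, mcmc.burn_in, mcmc.thin, s,
            g, a, sg, sa, mu_hi, mcmc.prior_log_sd,
        )
        chains.append(draws)
    theta = np.stack(chains)
    f_draws = np.exp(theta[:, :, 0])
    ds = az.convert_to_dataset({"f": f_draws[:, :, None]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(np.asarray(az.rhat(ds)["f"]).max())
        ess = float(np.asarray(az.ess(ds)["f"]).min())
    diagnostics = {"max_rhat": rhat, "min_ess": ess}
    if rhat > mcmc.rhat_threshold:
        raise ConvergenceError(
            f"class {klass!r}: split-R-hat {rhat:.3f} exceeds "
            f"{mcmc.rhat_threshold}", diagnostics=diagnostics,
        )
    flat = f_draws.ravel()
    lo, hi = np.quantile(flat, [0.025, 0.975])
    return FactorPosterior(
        species_class=klass, samples=flat, mean=float(flat.mean()),
        ci_low=float(lo), ci_high=float(hi), diagnostics=diagnostics,
    )
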