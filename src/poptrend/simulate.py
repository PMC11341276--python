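"""Synthetic count series and parallel count pairs with known truth.

The generator emulates the heterogeneity the method is built for: mixed
aerial/ground platforms with a known conversion bias, mixed statistical
methods, irregular census dates (fractional years allowed), and per-date
precision regimes (reported as a 95% CI, an se, a cv, or nothing at all).
Truth is returned alongside so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_io import CountRecord, CountSeries
from .conversion import ParallelPair
from .errors import InvalidArgumentError
from .precision import StandardizedCount, ci_to_sigma

__all__ = ["SimScenario", "simulate_series", "simulate_pairs"]

_Z95 = 1.96


@dataclass(frozen=True)
class SimScenario:
    """Ground truth and observation design for one simulated series.

    ``rates`` are piecewise-constant annual relative growth rates; segment i
    applies up to ``change_dates[i]`` (the last rate extends to the end).
    ``method_schedule`` gives (field_method, stat_method) per census date, or
    one pair for all dates.  ``cv`` sets the observation noise sd as a
    fraction of the expected count (scalar or per date) and ``report`` how
    that precision is written into the records ('ci95', 'se', 'cv', 'none').
    ``conversion_truth`` maps species class to the true aerial-to-ground
    factor biasing aerial observations (expectation N/f).
    """

    n0: float
    census_dates: tuple[float, ...]
    rates: tuple[float, ...] = (0.0,)
    change_dates: tuple[float, ...] = ()
    method_schedule: object = ("ground", "sample")
    cv: object = 0.1
    report: object = "ci95"
    conversion_truth: dict = field(default_factory=dict)
    species_class: str = "large_light_brown"
    site: str = "simsite"
    species: str = "simulated species"
    noise: str = "normal"  # or "lognormal" for a misspecification check
    seed: int = 0

    def __post_init__(self):
        if not self.n0 > 0:
            raise InvalidArgumentError("n0 must be > 0")
        d = np.asarray(self.census_dates, dtype=float)
        if len(d) < 2 or np.any(np.diff(d) <= 0):
            raise InvalidArgumentError("census_dates must be strictly increasing")
        if len(self.rates) != len(self.change_dates) + 1:
            raise InvalidArgumentError(
                "need len(rates) == len(change_dates) + 1")
        if not np.all(np.isfinite(np.asarray(self.rates))):
            raise InvalidArgumentError("rates must be finite")
        if self.noise not in ("normal", "lognormal"):
            raise InvalidArgumentError("noise must be 'normal' or 'lognormal'")


def _rate_at(scenario: SimScenario, t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(np.asarray(scenario.change_dates), t, side="right")
    return np.asarray(scenario.rates)[idx]


def _true_n(scenario: SimScenario, t: np.ndarray) -> np.ndarray:
    """N(t) = N0 * exp(integral of r from the first census date to t)."""
    t0 = scenario.census_dates[0]
    knots = np.concatenate(
        [[t0], [c for c in scenario.change_dates if c > t0], [np.inf]])
    out = np.empty(len(t))
    for k, tk in enumerate(t):
        log_growth = 0.0
        for a, b in zip(knots[:-1], knots[1:]):
            if tk <= a:
                break
            seg_end = min(tk, b)
            r = _rate_at(scenario, np.array([a]))[0]
            log_growth += r * (seg_end - a)
            if seg_end == tk:
                break
        out[k] = scenario.n0 * np.exp(log_growth)
    return out


def _per_date(value, n):
    arr = np.asarray(value if np.ndim(value) else [value] * n)
    if len(arr) != n:
        raise InvalidArgumentError(
            f"per-date setting has length {len(arr)}, expected {n}")
    return arr


def simulate_series(scenario: SimScenario):
    """Generate one count series plus its truth table.

    Returns ``(CountSeries, truth)`` where truth is a DataFrame with columns
    ``date, true_N, true_r``.  Ground observations have expectation N(t),
    aerial ones N(t)/f with f the class's true conversion factor; noise is
    normal (sd = cv * expectation) floored at zero.
    """
    rng = np.random.default_rng(scenario.seed)
    dates = np.asarray(scenario.census_dates, dtype=float)
    n = len(dates)
    truth_n = _true_n(scenario, dates)
    truth_r = _rate_at(scenario, dates)
    cvs = _per_date(scenario.cv, n).astype(float)
    reports = _per_date(scenario.report, n)
    sched = scenario.method_schedule
    if isinstance(sched, tuple) and len(sched) == 2 and isinstance(sched[0], str):
        sched = [sched] * n
    sched = list(sched)
    if len(sched) != n:
        raise InvalidArgumentError("method_schedule length mismatch")

    f = scenario.conversion_truth.get(scenario.species_class, 1.0)
    records = []
    for i in range(n):
        field_method, stat_method = sched[i]
        expect = truth_n[i] / f if field_method == "aerial" else truth_n[i]
        sd = cvs[i] * expect
        if scenario.noise == "normal":
            obs = expect + sd * rng.standard_normal()
        else:
            obs = expect * rng.lognormal(-0.5 * np.log1p(cvs[i] ** 2),
                                         np.sqrt(np.log1p(cvs[i] ** 2)))
        obs = max(obs, 0.0)
        kind, values = reports[i], ()
        if kind == "ci95":
            values = (max(obs - _Z95 * sd, 0.0), obs + _Z95 * sd)
        elif kind == "se":
            values = (sd,)
        elif kind == "cv":
            values = (cvs[i],)
        elif kind != "none":
            raise InvalidArgumentError(f"unknown report kind {kind!r}")
        records.append(CountRecord(
            site=scenario.site, species=scenario.species, date=float(dates[i]),
            field_method=field_method, stat_method=stat_method,
            count=float(obs), precision_kind=kind,
            precision_values=tuple(float(v) for v in values),
        ))
    series = CountSeries(site=scenario.site, species=scenario.species,
                         records=tuple(records))
    truth = pd.DataFrame({"date": dates, "true_N": truth_n, "true_r": truth_r})
    return series, truth


def _std_count(site, klass, date, method, obs, sd):
    lo, hi = max(obs - _Z95 * sd, 0.0), obs + _Z95 * sd
    rec = CountRecord(
        site=site, species=f"class:{klass}", date=date, field_method=method,
        stat_method="sample", count=float(obs), precision_kind="ci95",
        precision_values=(float(lo), float(hi)),
    )
    return StandardizedCount(record=rec, ci_low=lo, ci_high=hi,
                             sigma=ci_to_sigma(lo, hi))


def simulate_pairs(class_truth: dict, n_pairs: int, cv: float = 0.1,
                   seed: int = 0, mu_median: float = 500.0,
                   mu_log_sd: float = 0.5) -> list[ParallelPair]:
    """Parallel ground/aerial pairs with known per-class conversion factors.

    Latent true ground-scale abundances are lognormal around ``mu_median``;
    the ground observation is normal around mu, the aerial one around mu/f,
    both with sd = cv * expectation and carrying exact 95% CIs.
    """
    if n_pairs < 2:
        raise InvalidArgumentError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    pairs = []
    for klass, f in sorted(class_truth.items()):
        if not f > 0:
            raise InvalidArgumentError(f"factor for {klass!r} must be > 0")
        for j in range(n_pairs):
            mu = rng.lognormal(np.log(mu_median), mu_log_sd)
            sd_g, sd_a = cv * mu, cv * mu / f
            g = max(mu + sd_g * rng.standard_normal(), 0.0)
            a = max(mu / f + sd_a * rng.standard_normal(), 0.0)
            date = 2000.0 + j / 365.25
            pairs.append(ParallelPair(
                species_class=klass, site="simsite", date=date,
                ground=_std_count("simsite", klass, date, "ground", g, sd_g),
                aerial=_std_count("simsite", klass, date, "aerial", a, sd_a),
            ))
    return pairs
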