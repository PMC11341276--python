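"""Standardize every count's precision to a 95% interval and an observation sd.

Heterogeneous census archives report precision as a 95% CI, a standard
error, a variance, a coefficient of variation — or not at all.  This module
reduces all of them to one common currency, the 95% interval, applying
heuristic defaults where no precision was reported:

* total counts: asymmetric ``[0.95*C, 1.20*C]`` — a total count is close to
  a lower bound on true abundance (undercounting is far more likely than
  double-counting);
* expert guesstimates: ``[0.80*C, 1.20*C]``;
* sample counts with no reported precision: a configurable wide relative
  interval (default +/-100% of the count), flagged with a warning — sampled
  estimates should normally come with their own precision.

Negative lower bounds are floored at 0.01 and a zero count (local
extinction) receives the interval ``[0, 0.01]``.  The observation standard
deviation is then ``sigma = (hi - lo) / 3.93``, the normal-theory width of
a 95% interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .count_io import CSV_COLUMNS, CountRecord, CountSeries
from .errors import FormatError, InvalidIntervalError

__all__ = [
    "CI_WIDTH_FACTOR",
    "StandardizedCount",
    "StandardizedSeries",
    "standardize_ci",
    "standardize_series",
    "ci_to_sigma",
    "write_standardized",
    "read_standardized",
]

log = logging.getLogger(__name__)

#: Width of a normal 95% interval in sd units (kept at the conventional 3.93).
CI_WIDTH_FACTOR = 3.93

#: Lower-bound floor replacing negative (or zero, post-extinction) bounds.
LOWER_FLOOR = 0.01

#: Floor for sigma when an interval is degenerate, the extinction-case value.
SIGMA_FLOOR = LOWER_FLOOR / CI_WIDTH_FACTOR

#: Default relative half-width of the 95% CI for sample counts lacking any
#: precision measure (1.0 = +/-100% of the count).
DEFAULT_SAMPLE_REL_CI = 1.0

_Z95 = 1.96


@dataclass(frozen=True)
class StandardizedCount:
    """A count carried with its standardized 95% interval and derived sigma.

    ``scale`` records which field method's scale the values are currently
    expressed in; it starts as the record's own field method and is updated
    by harmonization (the record keeps the platform that made the count).
    """

    record: CountRecord
    ci_low: float
    ci_high: float
    sigma: float
    notes: tuple[str, ...] = ()
    scale: str = ""

    def __post_init__(self):
        if not self.scale:
            object.__setattr__(self, "scale", self.record.field_method)

    @property
    def count(self) -> float:
        return self.record.count

    @property
    def date(self) -> float:
        return self.record.date

    @property
    def field_method(self) -> str:
        return self.record.field_method


@dataclass(frozen=True)
class StandardizedSeries:
    """A count series whose records all carry standardized intervals."""

    site: str
    species: str
    counts: tuple[StandardizedCount, ...]

    def __len__(self):
        return len(self.counts)

    @property
    def dates(self):
        return [c.date for c in self.counts]


def ci_to_sigma(ci_low: float, ci_high: float,
                floor: float = SIGMA_FLOOR) -> float:
    """Observation sd from a 95% interval: ``(hi - lo) / 3.93``.

    Degenerate intervals return ``floor`` so the observation likelihood
    never collapses to a point mass.
    """
    if ci_high < ci_low:
        raise InvalidIntervalError(
            f"interval upper bound {ci_high} below lower bound {ci_low}"
        )
    sigma = (ci_high - ci_low) / CI_WIDTH_FACTOR
    return sigma if sigma > 0 else floor


def standardize_ci(record: CountRecord,
                   sample_rel_ci: float = DEFAULT_SAMPLE_REL_CI
                   ) -> StandardizedCount:
    """Apply the interval-construction rules to one count record.

    Rules, in order: a supplied 95% CI is used as given; se / variance / cv
    are converted through ``count +/- 1.96*se``; precision-free totals get
    ``[0.95C, 1.20C]``, guesstimates ``[0.80C, 1.20C]`` and sample counts the
    configurable ``count * (1 +/- sample_rel_ci)``.  Then negative lower
    bounds are floored at 0.01, a zero count yields [0, 0.01], and sigma is
    derived from the final interval.  Every repair is recorded in ``notes``.
    """
    c = record.count
    kind = record.precision_kind
    notes: list[str] = []

    if kind == "ci95":
        lo, hi = record.precision_values
    elif kind in ("se", "variance", "cv"):
        (v,) = record.precision_values
        if kind == "variance":
            se = math.sqrt(v)
        elif kind == "cv":
            se = v * c
        else:
            se = v
        lo, hi = c - _Z95 * se, c + _Z95 * se
        notes.append(f"ci from {kind} ({v:g}): count +/- 1.96*se")
    else:  # no precision information
        if record.stat_method == "total":
            lo, hi = 0.95 * c, 1.20 * c
            notes.append("default total-count interval [0.95C, 1.20C]")
        elif record.stat_method == "guesstimate":
            lo, hi = 0.80 * c, 1.20 * c
            notes.append("default guesstimate interval [0.80C, 1.20C]")
        else:  # sample count without precision: wide default, warn loudly
            lo = c * (1.0 - sample_rel_ci)
            hi = c * (1.0 + sample_rel_ci)
            notes.append(
                f"sample count without precision: default +/-{sample_rel_ci:.0%} "
                f"interval applied — supply a real precision measure if possible"
            )
            log.warning(
                "%s/%s @ %s: sample count %g has no precision measure; "
                "using default +/-%.0f%% interval",
                record.site, record.species, record.date, c,
                100 * sample_rel_ci,
            )

    if c == 0:
        # local extinction: [0, 0.01]
        lo, hi = 0.0, LOWER_FLOOR
        notes.append("zero count: extinction interval [0, 0.01]")
    elif lo < 0:
        lo = LOWER_FLOOR
        notes.append("negative lower bound floored at 0.01")
        if hi < lo:
            hi = lo
    sigma = ci_to_sigma(lo, hi)
    for n in notes:
        log.debug("%s/%s @ %s: %s", record.site, record.species,
                  record.date, n)
    return StandardizedCount(record=record, ci_low=lo, ci_high=hi,
                             sigma=sigma, notes=tuple(notes))


def standardize_series(series: CountSeries,
                       sample_rel_ci: float = DEFAULT_SAMPLE_REL_CI
                       ) -> StandardizedSeries:
    """Standardize every record of a series."""
    return StandardizedSeries(
        site=series.site,
        species=series.species,
        counts=tuple(standardize_ci(r, sample_rel_ci) for r in series.records),
    )


_STD_COLUMNS = CSV_COLUMNS + ["ci_low", "ci_high", "sigma"]


def write_standardized(series_list, path) -> None:
    """Write standardized (or harmonized) series: input schema + ci/sigma."""
    if isinstance(series_list, StandardizedSeries):
        series_list = [series_list]
    rows = []
    for s in series_list:
        for c in s.counts:
            r = c.record
            vals = list(r.precision_values) + [None, None]
            rows.append({
                "site": r.site, "species": r.species, "date": r.date,
                "field_method": r.field_method, "stat_method": r.stat_method,
                "count": r.count, "precision_kind": r.precision_kind,
                "precision_value_1": vals[0], "precision_value_2": vals[1],
                "ci_low": c.ci_low, "ci_high": c.ci_high, "sigma": c.sigma,
            })
    pd.DataFrame(rows, columns=_STD_COLUMNS).to_csv(path, index=False)


def read_standardized(path) -> list[StandardizedSeries]:
    """Read series written by :func:`write_standardized`."""
    df = pd.read_csv(path, dtype={"site": str, "species": str})
    missing = [c for c in _STD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    by_key: dict[tuple[str, str], list[StandardizedCount]] = {}
    for row in df.to_dict("records"):
        kind = str(row["precision_kind"]).strip().lower()
        n_vals = {"ci95": 2, "se": 1, "variance": 1, "cv": 1, "none": 0}[kind]
        fm = row["field_method"]
        fm = "" if fm is None or (isinstance(fm, float) and math.isnan(fm)) \
            else str(fm).strip().lower()
        rec = CountRecord(
            site=str(row["site"]).strip(), species=str(row["species"]).strip(),
            date=float(row["date"]), field_method=fm,
            stat_method=str(row["stat_method"]).strip().lower(),
            count=float(row["count"]), precision_kind=kind,
            precision_values=tuple(
                float(row[f"precision_value_{i + 1}"]) for i in range(n_vals)),
        )
        by_key.setdefault((rec.site, rec.species), []).append(StandardizedCount(
            record=rec, ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]), sigma=float(row["sigma"]),
        ))
    return [
        StandardizedSeries(site=site, species=species,
                           counts=tuple(sorted(cs, key=lambda c: c.date)))
        for (site, species), cs in sorted(by_key.items())
    ]
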