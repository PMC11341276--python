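"""Reading, validating and writing wildlife count series.

A *count record* is one census observation: site, species, date (as a
possibly fractional year), field method (aerial or ground platform),
statistical method (total count, sample count, or expert guesstimate), the
count itself, and whatever precision information accompanied it (a 95% CI,
a standard error, a variance, a coefficient of variation, or nothing).

Records are grouped into *count series* — one site x species combination,
sorted by date — which are the unit of trend analysis.  A series must hold
at least ``min_counts`` records (default 4) to support trend inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    FormatError,
    IneligibleSeriesError,
    InvalidArgumentError,
    MalformedRowsError,
)

__all__ = [
    "FIELD_METHODS",
    "STAT_METHODS",
    "PRECISION_KINDS",
    "CountRecord",
    "CountSeries",
    "fractional_year",
    "read_counts",
    "write_counts",
    "validate_series",
    "DEFAULT_MIN_COUNTS",
]

FIELD_METHODS = ("aerial", "ground", "")  # "" = unset (allowed for guesstimates)
STAT_METHODS = ("total", "sample", "guesstimate")
PRECISION_KINDS = ("ci95", "se", "variance", "cv", "none")

#: Minimum number of records for a series to support trend inference.
DEFAULT_MIN_COUNTS = 4

CSV_COLUMNS = [
    "site", "species", "date", "field_method", "stat_method", "count",
    "precision_kind", "precision_value_1", "precision_value_2",
]

#: how many precision values each kind carries
_N_VALUES = {"ci95": 2, "se": 1, "variance": 1, "cv": 1, "none": 0}


def fractional_year(year: int, month: int | None = None) -> float:
    """Encode a (year, month) date as a fractional year.

    Month ``m`` maps to ``year + (m - 0.5)/12`` (mid-month convention), so
    February 2000 becomes 2000.125.  Without a month the plain year is
    returned.
    """
    if month is None:
        return float(year)
    if not 1 <= month <= 12:
        raise InvalidArgumentError(f"month must be in 1..12, got {month}")
    return year + (month - 0.5) / 12.0


@dataclass(frozen=True)
class CountRecord:
    """One census observation with method metadata and raw precision."""

    site: str
    species: str
    date: float
    field_method: str
    stat_method: str
    count: float
    precision_kind: str = "none"
    precision_values: tuple[float, ...] = ()

    def __post_init__(self):
        if self.field_method not in FIELD_METHODS:
            raise InvalidArgumentError(
                f"field_method must be one of {FIELD_METHODS}, "
                f"got {self.field_method!r}"
            )
        if self.stat_method not in STAT_METHODS:
            raise InvalidArgumentError(
                f"stat_method must be one of {STAT_METHODS}, "
                f"got {self.stat_method!r}"
            )
        if self.precision_kind not in PRECISION_KINDS:
            raise InvalidArgumentError(
                f"precision_kind must be one of {PRECISION_KINDS}, "
                f"got {self.precision_kind!r}"
            )
        if not (math.isfinite(self.count) and self.count >= 0):
            raise InvalidArgumentError(f"count must be >= 0, got {self.count}")
        if not math.isfinite(self.date):
            raise InvalidArgumentError(f"date must be finite, got {self.date}")
        n_expected = _N_VALUES[self.precision_kind]
        if len(self.precision_values) != n_expected:
            raise InvalidArgumentError(
                f"precision_kind {self.precision_kind!r} requires "
                f"{n_expected} value(s), got {len(self.precision_values)}"
            )
        if any(not (math.isfinite(v) and v >= 0) for v in self.precision_values):
            raise InvalidArgumentError("precision values must be >= 0 and finite")
        if self.precision_kind == "ci95":
            lo, hi = self.precision_values
            if lo > hi:
                raise InvalidArgumentError(
                    f"ci95 bounds must satisfy low <= high, got [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class CountSeries:
    """Ordered records for one site x species."""

    site: str
    species: str
    records: tuple[CountRecord, ...] = field(default_factory=tuple)

    def __post_init__(self):
        for rec in self.records:
            if rec.site != self.site or rec.species != self.species:
                raise InvalidArgumentError(
                    f"record for {rec.site}/{rec.species} does not belong "
                    f"to series {self.site}/{self.species}"
                )
        dates = [r.date for r in self.records]
        if any(b < a for a, b in zip(dates, dates[1:])):
            object.__setattr__(
                self, "records",
                tuple(sorted(self.records, key=lambda r: r.date)),
            )

    def __len__(self):
        return len(self.records)

    @property
    def dates(self):
        return [r.date for r in self.records]


def _parse_row(row, rownum):
    """Build a CountRecord from one CSV row; raise ValueError with detail."""
    def _text(name, allowed=None, allow_empty=False):
        v = row.get(name)
        v = "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v).strip().lower()
        if not v and not allow_empty:
            raise ValueError(f"missing value for {name!r}")
        if allowed is not None and v not in allowed:
            raise ValueError(f"{name!r} must be one of {allowed}, got {v!r}")
        return v

    def _num(name):
        v = row.get(name)
        try:
            out = float(v)
        except (TypeError, ValueError):
            raise ValueError(f"unparseable {name!r}: {v!r}") from None
        if math.isnan(out):
            raise ValueError(f"unparseable {name!r}: {v!r}")
        return out

    site = str(row["site"]).strip()
    species = str(row["species"]).strip()
    if not site or site.lower() == "nan":
        raise ValueError("missing value for 'site'")
    if not species or species.lower() == "nan":
        raise ValueError("missing value for 'species'")
    kind = _text("precision_kind", PRECISION_KINDS, allow_empty=True) or "none"
    n_vals = _N_VALUES[kind]
    values = tuple(
        _num(f"precision_value_{i + 1}") for i in range(n_vals)
    )
    return CountRecord(
        site=site,
        species=species,
        date=_num("date"),
        field_method=_text("field_method", FIELD_METHODS, allow_empty=True),
        stat_method=_text("stat_method", STAT_METHODS),
        count=_num("count"),
        precision_kind=kind,
        precision_values=values,
    )


def read_counts(path) -> list[CountSeries]:
    """Read a counts CSV and group records into per-site x species series.

    The file must carry the columns ``site, species, date, field_method,
    stat_method, count, precision_kind, precision_value_1,
    precision_value_2``.  Malformed rows are collected and reported together
    in a :class:`MalformedRowsError` carrying 1-based data-row numbers.
    """
    df = pd.read_csv(path, dtype={"site": str, "species": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records, row_errors = [], []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            records.append(_parse_row(row, i))
        except (ValueError, InvalidArgumentError) as exc:
            row_errors.append((i, str(exc)))
    if row_errors:
        raise MalformedRowsError(row_errors)
    return group_records(records)


def group_records(records) -> list[CountSeries]:
    """Partition records into date-sorted series, one per site x species."""
    groups: dict[tuple[str, str], list[CountRecord]] = {}
    for rec in records:
        groups.setdefault((rec.site, rec.species), []).append(rec)
    return [
        CountSeries(site=site, species=species,
                    records=tuple(sorted(recs, key=lambda r: r.date)))
        for (site, species), recs in sorted(groups.items())
    ]


def write_counts(series_list, path) -> None:
    """Write series back to the input CSV schema (lossless round-trip)."""
    rows = []
    for s in ([series_list] if isinstance(series_list, CountSeries) else series_list):
        for r in s.records:
            vals = list(r.precision_values) + [None, None]
            rows.append({
                "site": r.site, "species": r.species, "date": r.date,
                "field_method": r.field_method, "stat_method": r.stat_method,
                "count": r.count, "precision_kind": r.precision_kind,
                "precision_value_1": vals[0], "precision_value_2": vals[1],
            })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def validate_series(series: CountSeries,
                    min_counts: int = DEFAULT_MIN_COUNTS) -> CountSeries:
    """Enforce the minimum-count eligibility rule (default 4 records).

    A stricter rule may be adopted by raising ``min_counts``; relaxing it
    below 4 is refused because shorter series cannot support a trend.
    """
    if min_counts < DEFAULT_MIN_COUNTS:
        raise InvalidArgumentError(
            f"min_counts may only be raised above {DEFAULT_MIN_COUNTS}"
        )
    if len(series) < min_counts:
        raise IneligibleSeriesError(series.site, series.species,
                                    len(series), min_counts)
    return series
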