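"""Reference tables: species classes, aerial/ground conversion factors, r_max.

Large savanna herbivores are grouped into five detectability classes that
share an aerial/ground conversion factor (body size and coat colour drive
detection from the air).  Each species profile also carries the adult female
body mass and the demographic ceiling on the annual relative growth rate,
``r_max``, either taken from the literature or derived from body mass with
the allometric relation ``r_max = 1.375 * W**-0.315`` (W in kg).

The packaged tables are plain CSV files and can be replaced wholesale by
user-supplied tables with the same schema (pass ``path=`` to the loaders).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import InvalidArgumentError, LookupFailedError, MissingDataError

__all__ = [
    "SPECIES_CLASSES",
    "SpeciesProfile",
    "ConversionEntry",
    "rmax_from_mass",
    "load_conversion_factors",
    "get_conversion_factor",
    "load_species_profiles",
    "get_species_profile",
    "get_rmax",
]

#: The five detectability classes used across sites.
SPECIES_CLASSES = (
    "medium_light_brown",   # light/brown coat, 20-150 kg (impala, tiang, kob...)
    "large_light_brown",    # light/brown coat, >150 kg (roan, wildebeest, eland...)
    "large_dark",           # dark coat, >150 kg (buffalo, sable)
    "giraffe",
    "elephant",
)

#: Allometric coefficients for r_max as a function of adult female mass.
RMAX_COEF = 1.375
RMAX_EXPONENT = -0.315


@dataclass(frozen=True)
class SpeciesProfile:
    """Reference profile for one species.

    ``female_body_mass`` (kg) and ``r_max`` (per year) may be ``None`` for
    species that have a class assignment but no published demographic data;
    :func:`get_rmax` then requires the user to supply them.
    """

    species_name: str
    species_class: str
    female_body_mass: float | None = None
    r_max: float | None = None
    r_max_source: str | None = None  # "table" | "formula" | "user"
    preferred_field_method: str = ""  # "aerial" | "ground" | "" (unset)

    def __post_init__(self):
        if self.species_class not in SPECIES_CLASSES:
            raise InvalidArgumentError(
                f"unknown species class {self.species_class!r}"
            )
        if self.female_body_mass is not None and not self.female_body_mass > 0:
            raise InvalidArgumentError("female_body_mass must be > 0")
        if self.r_max is not None and not self.r_max > 0:
            raise InvalidArgumentError("r_max must be > 0")


@dataclass(frozen=True)
class ConversionEntry:
    """Multiplicative factor turning an aerial count into its ground equivalent."""

    species_class: str
    factor: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (0 < self.ci_low <= self.factor <= self.ci_high):
            raise InvalidArgumentError(
                f"require 0 < ci_low <= factor <= ci_high, got "
                f"({self.ci_low}, {self.factor}, {self.ci_high})"
            )


def _packaged(name: str) -> Path:
    return resources.files("poptrend.data").joinpath(name)


def rmax_from_mass(mass_kg: float) -> float:
    """Annual maximum relative growth rate from adult female body mass.

    Uses the allometric scaling ``1.375 * W**-0.315`` with W in kg.

    >>> round(rmax_from_mass(127), 3)
    0.299
    """
    if not mass_kg > 0:
        raise InvalidArgumentError(f"body mass must be > 0, got {mass_kg}")
    return RMAX_COEF * mass_kg ** RMAX_EXPONENT


def load_conversion_factors(path=None) -> dict[str, ConversionEntry]:
    """Load the conversion-factor table (packaged default or user override)."""
    src = _packaged("conversion_factors.csv") if path is None else path
    with resources.as_file(src) if path is None else _nullcontext(src) as p:
        df = pd.read_csv(p)
    required = {"species_class", "factor", "ci_low", "ci_high"}
    if not required.issubset(df.columns):
        raise MissingDataError(
            f"conversion table lacks columns {sorted(required - set(df.columns))}"
        )
    return {
        row.species_class: ConversionEntry(
            species_class=row.species_class,
            factor=float(row.factor),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
        )
        for row in df.itertuples()
    }


def get_conversion_factor(species_class: str, table=None) -> ConversionEntry:
    """Return the conversion entry for a species class.

    ``table`` may be a dict from :func:`load_conversion_factors`; the packaged
    defaults are used when omitted.
    """
    if table is None:
        table = load_conversion_factors()
    try:
        return table[species_class]
    except KeyError:
        raise LookupFailedError(
            f"no conversion factor for class {species_class!r}; "
            f"known classes: {sorted(table)}"
        ) from None


def load_species_profiles(path=None) -> dict[str, SpeciesProfile]:
    """Load species profiles keyed by lower-cased species name."""
    src = _packaged("species_classes.csv") if path is None else path
    with resources.as_file(src) if path is None else _nullcontext(src) as p:
        df = pd.read_csv(p)
    required = {"species", "mass_kg", "class", "rmax", "rmax_source",
                "preferred_method"}
    if not required.issubset(df.columns):
        raise MissingDataError(
            f"species table lacks columns {sorted(required - set(df.columns))}"
        )
    df = df.rename(columns={"class": "species_class"})
    profiles = {}
    for row in df.itertuples():
        name = str(row.species).strip().lower()
        profiles[name] = SpeciesProfile(
            species_name=name,
            species_class=str(row.species_class).strip(),
            female_body_mass=None if pd.isna(row.mass_kg) else float(row.mass_kg),
            r_max=None if pd.isna(row.rmax) else float(row.rmax),
            r_max_source=None if pd.isna(row.rmax_source) else str(row.rmax_source),
            preferred_field_method="" if pd.isna(row.preferred_method)
            else str(row.preferred_method),
        )
    return profiles


def get_species_profile(species: str, table=None) -> SpeciesProfile:
    """Case-insensitive exact lookup of a species profile."""
    if table is None:
        table = load_species_profiles()
    key = species.strip().lower()
    try:
        return table[key]
    except KeyError:
        raise LookupFailedError(
            f"unknown species {species!r}; supply a SpeciesProfile with "
            f"body mass and class explicitly"
        ) from None


def get_rmax(profile: SpeciesProfile) -> float:
    """Resolve r_max for a profile.

    Precedence: an explicit user value (``r_max_source == 'user'``) wins,
    then any tabulated value, then the allometric formula applied to the
    body mass.  Raises :class:`MissingDataError` when neither a value nor a
    mass is available.
    """
    if profile.r_max is not None:
        return profile.r_max
    if profile.female_body_mass is not None:
        return rmax_from_mass(profile.female_body_mass)
    raise MissingDataError(
        f"species {profile.species_name!r} has neither a tabulated r_max "
        f"nor a body mass; supply one of them"
    )


class _nullcontext:
    """Minimal context manager wrapping a plain path."""

    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False
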