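import numpy as np
import pytest
from hypothesis import settings

import poptrend as pt

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quick_mcmc():
    """Sampler settings small enough for unit tests but still diagnosable."""
    return dict(chains=2, iterations=6000, burn_in=3000, thin=3)


@pytest.fixture(scope="session")
def noisy_series():
    """A fixed noisy synthetic series used across trend tests."""
    scen = pt.SimScenario(
        n0=1500.0,
        census_dates=tuple(np.linspace(1985.0, 2009.0, 18)),
        rates=(0.06, -0.08, 0.04),
        change_dates=(1993.0, 2001.0),
        cv=0.15,
        seed=20240822,
    )
    series, truth = pt.simulate_series(scen)
    return pt.standardize_series(series), truth


def make_series(records):
    site, species = records[0].site, records[0].species
    return pt.CountSeries(site=site, species=species, records=tuple(records))


def rec(date, count, site="nazinga", species="roan", field="ground",
        stat="sample", kind="none", values=()):
    return pt.CountRecord(site=site, species=species, date=date,
                          field_method=field, stat_method=stat, count=count,
                          precision_kind=kind, precision_values=values)
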