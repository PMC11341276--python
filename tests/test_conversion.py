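"""Aerial/ground harmonization and conversion-factor estimation."""

import numpy as np
import pytest

import poptrend as pt
from poptrend.conversion import McmcConfig
from poptrend.errors import InvalidArgumentError, MissingDataError

ROAN = pt.get_species_profile("roan")          # large_light_brown, f = 2.302
ELEPHANT = pt.get_species_profile("elephant")  # f = 0.659


def mixed_series(methods, counts=None, species="roan", seed=0):
    counts = counts or [400 + 10 * i for i in range(len(methods))]
    recs = [
        pt.CountRecord(site="s", species=species, date=2000.0 + i,
                       field_method=m, stat_method="sample", count=float(c),
                       precision_kind="ci95",
                       precision_values=(0.8 * c, 1.2 * c))
        for i, (m, c) in enumerate(zip(methods, counts))
    ]
    return pt.standardize_series(
        pt.CountSeries(site="s", species=species, records=tuple(recs)))


class TestHarmonize:
    def test_aerial_count_multiplied_into_ground_scale(self):
        std = mixed_series(["aerial", "ground"], [406, 900])
        out = pt.harmonize_series(std, ROAN, target="ground")
        assert out.counts[0].count == pytest.approx(406 * 2.302)
        assert out.counts[1].count == 900  # already in target scale

    def test_ground_count_divided_into_aerial_scale(self):
        std = mixed_series(["ground", "aerial"], [100, 70],
                           species="elephant")
        out = pt.harmonize_series(std, ELEPHANT, target="aerial")
        assert out.counts[0].count == pytest.approx(100 / 0.659)

    def test_all_target_scale_is_identity(self):
        std = mixed_series(["ground", "ground", "ground"])
        out = pt.harmonize_series(std, ROAN, target="ground")
        assert out == std

    def test_auto_uses_preferred_method(self):
        std = mixed_series(["aerial", "ground", "ground"])
        out = pt.harmonize_series(std, ROAN, target="auto")  # prefers ground
        assert out.counts[0].count == pytest.approx(400 * 2.302)
        assert out.counts[1].count == 410

    def test_auto_falls_back_to_majority_method(self):
        prof = pt.SpeciesProfile("x", "large_light_brown",
                                 female_body_mass=250.0)
        std = mixed_series(["aerial", "aerial", "ground"])
        out = pt.harmonize_series(std, prof, target="auto")
        # majority is aerial: the ground record is divided by f
        assert out.counts[2].count == pytest.approx(420 / 2.302)

    def test_sigma_rederived_and_ci_scaled(self):
        std = mixed_series(["aerial", "ground"], [406, 900])
        out = pt.harmonize_series(std, ROAN, target="ground")
        c = out.counts[0]
        assert c.ci_low == pytest.approx(0.8 * 406 * 2.302)
        assert c.sigma == pytest.approx((c.ci_high - c.ci_low) / 3.93)
        assert c.ci_low < c.ci_high

    def test_round_trip_is_identity(self):
        std = mixed_series(["aerial", "ground", "aerial", "ground"])
        there = pt.harmonize_series(std, ROAN, target="ground")
        back = pt.harmonize_series(there, ROAN, target="aerial")
        again = pt.harmonize_series(back, ROAN, target="ground")
        for a, b in zip(there.counts, again.counts):
            assert b.count == pytest.approx(a.count, rel=1e-9)
            assert b.ci_low == pytest.approx(a.ci_low, rel=1e-9)
            assert b.ci_high == pytest.approx(a.ci_high, rel=1e-9)

    def test_unset_method_needing_conversion_is_an_error(self):
        std = mixed_series(["", "ground"])
        with pytest.raises(MissingDataError):
            pt.harmonize_series(std, ROAN, target="aerial")


class TestParallelPair:
    def test_rejects_counts_more_than_a_month_apart(self):
        (pair,) = pt.simulate_pairs({"giraffe": 3.0}, 2, seed=1)[:1]
        from dataclasses import replace
        far = replace(pair.aerial.record, date=pair.ground.date + 0.2)
        bad_aerial = replace(pair.aerial, record=far)
        with pytest.raises(InvalidArgumentError):
            pt.ParallelPair(species_class="giraffe", site="s",
                            date=pair.date, ground=pair.ground,
                            aerial=bad_aerial)


class TestFitConversionFactors:
    def test_recovers_simulated_factor(self, quick_mcmc):
        pairs = pt.simulate_pairs({"large_light_brown": 2.3}, 40, cv=0.1,
                                  seed=11)
        fp = pt.fit_conversion_factors(
            pairs, McmcConfig(seed=1, **quick_mcmc))["large_light_brown"]
        assert abs(fp.mean - 2.3) / 2.3 < 0.10
        assert fp.ci_low <= fp.mean <= fp.ci_high
        assert np.all(fp.samples > 0)

    def test_identity_calibration_concentrates_near_one(self, quick_mcmc):
        # aerial identical to ground with symmetric sigmas: f must sit at 1
        rng = np.random.default_rng(7)
        pairs = []
        for j in range(40):
            mu = rng.lognormal(np.log(500), 0.5)
            sd = 0.1 * mu
            rec = pt.CountRecord(site="s", species="class:giraffe",
                                 date=2000.0 + j / 400, field_method="ground",
                                 stat_method="sample", count=mu,
                                 precision_kind="ci95",
                                 precision_values=(mu - 1.96 * sd,
                                                   mu + 1.96 * sd))
            sc = pt.StandardizedCount(record=rec, ci_low=mu - 1.96 * sd,
                                      ci_high=mu + 1.96 * sd, sigma=sd)
            from dataclasses import replace
            aerial = replace(sc, record=replace(rec, field_method="aerial"),
                             scale="aerial")
            pairs.append(pt.ParallelPair(species_class="giraffe", site="s",
                                         date=rec.date, ground=sc,
                                         aerial=aerial))
        fp = pt.fit_conversion_factors(
            pairs, McmcConfig(seed=2, **quick_mcmc))["giraffe"]
        assert fp.ci_low < 1.0 < fp.ci_high
        assert abs(fp.mean - 1.0) < 0.05

    def test_more_pairs_narrow_the_interval(self, quick_mcmc):
        wide = pt.simulate_pairs({"elephant": 0.66}, 2, cv=0.15, seed=3)
        tight = pt.simulate_pairs({"elephant": 0.66}, 80, cv=0.15, seed=3)
        cfg = McmcConfig(seed=3, **quick_mcmc)
        w = pt.fit_conversion_factors(wide, cfg)["elephant"]
        t = pt.fit_conversion_factors(tight, cfg)["elephant"]
        assert (t.ci_high - t.ci_low) < (w.ci_high - w.ci_low)

    def test_single_pair_is_rejected(self, quick_mcmc):
        pairs = pt.simulate_pairs({"large_dark": 0.56}, 2, seed=4)[:1]
        with pytest.raises(InvalidArgumentError):
            pt.fit_conversion_factors(pairs, McmcConfig(seed=1, **quick_mcmc))

    def test_summary_round_trips_to_reference_entry(self, quick_mcmc):
        pairs = pt.simulate_pairs({"giraffe": 3.0}, 20, cv=0.1, seed=5)
        fp = pt.fit_conversion_factors(
            pairs, McmcConfig(seed=5, **quick_mcmc))["giraffe"]
        entry = fp.as_entry()
        assert entry.species_class == "giraffe"
        assert entry.ci_low <= entry.factor <= entry.ci_high
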