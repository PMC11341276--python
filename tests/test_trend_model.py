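"""State-space trend model: structure, inference behavior, invariants."""

import numpy as np
import pytest

import poptrend as pt
from poptrend.errors import (
    ExtrapolationError,
    InvalidArgumentError,
    ModelError,
)

from conftest import rec


def quick_cfg(quick_mcmc, **kw):
    kw.setdefault("use_rmax", False)
    kw.setdefault("seed", 0)
    return pt.TrendModelConfig(**quick_mcmc, **kw)


def std(records):
    return pt.standardize_series(
        pt.CountSeries(site=records[0].site, species=records[0].species,
                       records=tuple(records)))


class TestBuildModel:
    def test_k_dates_give_k_states_k_minus_1_rates(self, quick_mcmc):
        series = std([rec(2000.0 + i, 100, kind="ci95", values=(80, 120))
                      for i in range(5)])
        model = pt.build_model(series, quick_cfg(quick_mcmc))
        assert model.n_states == 5
        assert model.n_rates == 4
        assert np.allclose(model.dt, 1.0)

    def test_same_date_counts_share_one_state(self, quick_mcmc):
        series = std([
            rec(2000.0, 90, kind="ci95", values=(70, 110)),
            rec(2000.0, 110, kind="ci95", values=(95, 125)),
            rec(2003.0, 150, kind="ci95", values=(120, 180)),
        ])
        model = pt.build_model(series, quick_cfg(quick_mcmc))
        assert model.n_states == 2
        assert list(model.obs_date_index) == [0, 0, 1]
        # N_1 anchor is the precision-weighted mean of the two 2000 counts
        w1, w2 = (3.93 / 40) ** 2, (3.93 / 30) ** 2
        assert model.first_count == pytest.approx(
            (90 * w1 + 110 * w2) / (w1 + w2))

    def test_single_date_is_a_model_error(self, quick_mcmc):
        series = std([rec(2000.0, 90, kind="ci95", values=(70, 110))] * 2)
        with pytest.raises(ModelError):
            pt.build_model(series, quick_cfg(quick_mcmc))

    def test_plain_series_is_rejected(self, quick_mcmc):
        series = pt.CountSeries(site="nazinga", species="roan",
                                records=(rec(2000, 10), rec(2001, 11)))
        with pytest.raises(InvalidArgumentError):
            pt.build_model(series, quick_cfg(quick_mcmc))

    def test_rmax_requires_a_value(self):
        with pytest.raises(InvalidArgumentError):
            pt.TrendModelConfig(use_rmax=True)


class TestFitTrend:
    def test_constant_counts_cover_zero_growth(self, quick_mcmc):
        series = std([rec(1990.0 + 2 * i, 1000, kind="ci95",
                          values=(900, 1100)) for i in range(8)])
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc, seed=4))
        mr = pt.mean_growth_rate(fit)
        assert mr["low95"] < 0 < mr["high95"]
        assert abs(mr["mean"]) < 0.05

    def test_reproducible_given_seed(self, quick_mcmc, noisy_series):
        series, _ = noisy_series
        cfg = quick_cfg(quick_mcmc, seed=9)
        f1 = pt.fit_trend(series, cfg)
        f2 = pt.fit_trend(series, cfg)
        assert np.array_equal(f1.n_draws, f2.n_draws)
        assert np.array_equal(f1.r_draws, f2.r_draws)

    def test_all_abundance_draws_positive(self, quick_mcmc, noisy_series):
        series, _ = noisy_series
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc))
        assert np.all(fit.n_draws > 0)

    def test_rmax_caps_every_rate_draw(self, quick_mcmc):
        # a 6x jump over one year implies r = ln 6 = 1.79 >> r_max
        counts = [200, 210, 205, 1230, 1250, 1240]
        series = std([rec(2000.0 + i, c, kind="ci95",
                          values=(0.9 * c, 1.1 * c))
                      for i, c in enumerate(counts)])
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc, use_rmax=True,
                                             r_max=0.242, seed=2))
        assert np.all(fit.r_draws <= 0.242 + 1e-12)

    def test_diagnostics_present_and_reasonable(self, quick_mcmc,
                                                noisy_series):
        series, _ = noisy_series
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc, seed=1))
        assert fit.diagnostics["max_rhat"] < 1.1
        assert fit.diagnostics["min_ess"] > 50
        assert fit.converged

    def test_scale_equivariance(self, quick_mcmc):
        recs = [rec(2000.0 + i, c, kind="ci95", values=(0.85 * c, 1.2 * c))
                for i, c in enumerate([120, 100, 140, 160, 130, 170])]
        scaled = [rec(2000.0 + i, 10 * c, kind="ci95",
                      values=(8.5 * c, 12 * c))
                  for i, c in enumerate([120, 100, 140, 160, 130, 170])]
        cfg = quick_cfg(quick_mcmc, seed=6)
        f1, f2 = pt.fit_trend(std(recs), cfg), pt.fit_trend(std(scaled), cfg)
        m1 = f1.trajectory_summary().N_median.values
        m2 = f2.trajectory_summary().N_median.values
        assert np.allclose(m2 / m1, 10.0, rtol=0.05)
        r1 = f1.rates_summary().r_mean.values
        r2 = f2.rates_summary().r_mean.values
        assert np.allclose(r1, r2, atol=0.03)

    def test_smoothing_reduces_rate_roughness(self, quick_mcmc,
                                              noisy_series):
        series, _ = noisy_series
        smooth = pt.fit_trend(series, quick_cfg(quick_mcmc,
                                                smoothing_precision=100.0,
                                                seed=3))
        rough = pt.fit_trend(series, quick_cfg(quick_mcmc,
                                               smoothing_precision=1.0,
                                               seed=3))
        def total_variation(fit):
            r = np.median(fit.r_flat, axis=0)
            return np.abs(np.diff(r)).sum()
        assert total_variation(smooth) <= total_variation(rough)

    def test_subsampling_keeps_mean_r_consistent(self, quick_mcmc,
                                                 noisy_series):
        series, _ = noisy_series
        half = pt.StandardizedSeries(site=series.site, species=series.species,
                                     counts=series.counts[::2])
        cfg = quick_cfg(quick_mcmc, seed=8)
        full_mr = pt.mean_growth_rate(pt.fit_trend(series, cfg))
        half_mr = pt.mean_growth_rate(pt.fit_trend(half, cfg))
        assert full_mr["low95"] <= half_mr["high95"]
        assert half_mr["low95"] <= full_mr["high95"]


class TestMeanGrowthRate:
    def test_single_interval_equals_r1(self, quick_mcmc):
        series = std([rec(2000.0, 100, kind="ci95", values=(80, 120)),
                      rec(2004.0, 130, kind="ci95", values=(105, 155))])
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc, seed=5))
        mr = pt.mean_growth_rate(fit)
        assert np.allclose(mr["samples"], fit.r_flat[:, 0])

    def test_doubling_trajectory_gives_ln2_over_10(self, quick_mcmc):
        scen = pt.SimScenario(n0=1000.0,
                              census_dates=tuple(np.linspace(2000, 2010, 11)),
                              rates=(np.log(2) / 10,), cv=0.02, seed=12)
        series, _ = pt.simulate_series(scen)
        fit = pt.fit_trend(pt.standardize_series(series),
                           quick_cfg(quick_mcmc, seed=12))
        assert pt.mean_growth_rate(fit)["mean"] == pytest.approx(
            np.log(2) / 10, abs=0.02)

    def test_rise_then_fall_covers_zero(self, quick_mcmc):
        scen = pt.SimScenario(n0=800.0,
                              census_dates=tuple(np.linspace(2000, 2010, 11)),
                              rates=(0.1, -0.1), change_dates=(2005.0,),
                              cv=0.05, seed=13)
        series, _ = pt.simulate_series(scen)
        fit = pt.fit_trend(pt.standardize_series(series),
                           quick_cfg(quick_mcmc, seed=13))
        mr = pt.mean_growth_rate(fit)
        assert mr["low95"] < 0 < mr["high95"]


class TestTrajectoryAt:
    def test_count_date_query_matches_state_quantiles(self, quick_mcmc,
                                                      noisy_series):
        series, _ = noisy_series
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc, seed=2))
        out = pt.trajectory_at(fit, fit.dates)
        summary = fit.trajectory_summary()
        assert np.allclose(out.N_median, summary.N_median)
        assert np.allclose(out.N_low95, summary.N_low95)

    def test_midpoint_of_noise_free_doubling_is_geometric_mean(self,
                                                               quick_mcmc):
        scen = pt.SimScenario(n0=1000.0, census_dates=(2000.0, 2010.0),
                              rates=(np.log(2) / 10,), cv=0.02, seed=3)
        series, _ = pt.simulate_series(scen)
        fit = pt.fit_trend(pt.standardize_series(series),
                           quick_cfg(quick_mcmc, seed=3))
        mid = pt.trajectory_at(fit, [2005.0]).N_median[0]
        ends = fit.trajectory_summary().N_median.values
        assert mid == pytest.approx(np.sqrt(ends[0] * ends[1]), rel=0.03)

    def test_band_tighter_where_counts_are_dense_and_precise(self,
                                                             quick_mcmc):
        # Per draw the trajectory is log-linear inside an interval, so the
        # band inside a gap is governed by the gap's endpoints: a date pinned
        # by several precise counts beats the middle of a gap flanked by
        # single vague counts.
        recs = [rec(2000.0, c, kind="ci95", values=(0.95 * c, 1.05 * c))
                for c in (980, 1000, 1010, 995)]
        recs += [rec(2001.0, c, kind="ci95", values=(0.95 * c, 1.05 * c))
                 for c in (1005, 990)]
        recs += [rec(2011.0, 1000, kind="ci95", values=(500, 1500)),
                 rec(2012.0, 1000, kind="ci95", values=(500, 1500))]
        fit = pt.fit_trend(std(recs), quick_cfg(quick_mcmc, seed=7))
        at = pt.trajectory_at(fit, [2000.0, 2006.0])
        width = (at.N_high95 - at.N_low95).values
        assert width[1] > width[0]

    def test_extrapolation_refused(self, quick_mcmc, noisy_series):
        series, _ = noisy_series
        fit = pt.fit_trend(series, quick_cfg(quick_mcmc))
        with pytest.raises(ExtrapolationError):
            pt.trajectory_at(fit, [1970.0])
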