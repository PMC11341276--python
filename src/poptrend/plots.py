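"""Plotting helpers: trajectory with credible band, and rate series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_trajectory(std_series, fit, path=None, n_grid: int = 200):
    """Counts with 95% CI whiskers, posterior median and credible band."""
    from .trend_model import trajectory_at

    fig, ax = plt.subplots(figsize=(7, 4.5))
    grid = np.linspace(fit.dates[0], fit.dates[-1], n_grid)
    band = trajectory_at(fit, grid)
    ax.fill_between(band.date, band.N_low95, band.N_high95,
                    color="0.8", label="95% credible band")
    ax.plot(band.date, band.N_median, color="crimson", lw=1.8,
            label="posterior median")
    dates = [c.date for c in std_series.counts]
    counts = [c.count for c in std_series.counts]
    lo = [c.count - c.ci_low for c in std_series.counts]
    hi = [c.ci_high - c.count for c in std_series.counts]
    ax.errorbar(dates, counts, yerr=[lo, hi], fmt="o", ms=4, color="black",
                ecolor="0.4", elinewidth=1, capsize=2, label="counts (95% CI)")
    ax.set_xlabel("year")
    ax.set_ylabel("abundance")
    ax.set_title(f"{std_series.site} — {std_series.species}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_rates(fit, path=None):
    """Per-interval annual growth rate (posterior mean and 95% CrI)."""
    from .trend_model import mean_growth_rate

    rates = fit.rates_summary()
    mid = 0.5 * (rates.interval_start + rates.interval_end)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.errorbar(mid, rates.r_mean,
                yerr=[rates.r_mean - rates.r_low95,
                      rates.r_high95 - rates.r_mean],
                fmt="s", ms=4, color="navy", ecolor="0.5", capsize=2,
                label="interval r (95% CrI)")
    mr = mean_growth_rate(fit)
    ax.axhspan(mr["low95"], mr["high95"], color="orange", alpha=0.15)
    ax.axhline(mr["mean"], color="orange", lw=1.5,
               label=f"mean r = {mr['mean']:.3f}")
    if fit.config.use_rmax:
        ax.axhline(fit.config.r_max, color="red", ls="--", lw=1,
                   label=f"r_max = {fit.config.r_max:.3f}")
    ax.set_xlabel("year")
    ax.set_ylabel("annual relative growth rate r")
    ax.set_title(f"{fit.model.site} — {fit.model.species}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
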