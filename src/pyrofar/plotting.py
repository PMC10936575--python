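"""Figures: density pairs, exceedance/FAR panels, RR curves."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .attribution import AttributionCurve, BootstrapBands  # noqa: E402
from .density import DensityEstimate  # noqa: E402


def plot_density_pair(d0: DensityEstimate, d1: DensityEstimate):
    """Overlayed fire-size densities for the two scenarios."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(d0.grid, d0.density, color="tab:blue", label=d0.source_label)
    ax.plot(d1.grid, d1.density, color="tab:orange", label=d1.source_label)
    ax.set_xlabel("final fire size (ha)")
    ax.set_ylabel("density (per ha)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_attribution_panel(curve: AttributionCurve,
                           bands: BootstrapBands | None = None,
                           threshold: float | None = None):
    """p0, p1 and FAR against fire size on one panel."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(curve.grid, curve.p0, color="tab:blue",
            label=f"p0 ({curve.p0_label})")
    ax.plot(curve.grid, curve.p1, color="tab:orange",
            label=f"p1 ({curve.p1_label})")
    ax.plot(curve.grid, np.where(curve.valid_mask, curve.far, np.nan),
            color="tab:green", label="FAR")
    if bands is not None:
        ax.fill_between(bands.grid, bands.far_lo, bands.far_hi,
                        where=bands.available, color="tab:green", alpha=0.2,
                        label=f"FAR {bands.level:.0%} band")
    if threshold is not None:
        ax.axvline(threshold, color="grey", ls="--", lw=1,
                   label=f"threshold {threshold:,.0f} ha")
    ax.set_xlabel("fire size threshold (ha)")
    ax.set_ylabel("probability / FAR")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_rr(curve: AttributionCurve, threshold: float | None = None,
            log_scale: bool = False):
    """RR against fire size, optionally on a log axis (RR can span
    orders of magnitude in the upper tail)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    rr_vals = np.where(np.isfinite(curve.rr), curve.rr, np.nan)
    ax.plot(curve.grid, rr_vals, color="tab:red", label="RR")
    if threshold is not None:
        ax.axvline(threshold, color="grey", ls="--", lw=1,
                   label=f"threshold {threshold:,.0f} ha")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("fire size threshold (ha)")
    ax.set_ylabel("relative risk")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
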