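"""Matplotlib figures for gating, death fractions and dose-response."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gating import DeathGater, _as_xy
from .synth import DEATH_MODES
from .viability import DoseResponseFit

__all__ = ["plot_gating_scatter", "plot_death_fractions", "plot_dose_response"]

_MODE_COLORS = {
    "viable": "tab:blue",
    "apoptotic": "tab:green",
    "necrotic": "tab:red",
    "late_apoptotic": "gold",
}


def plot_gating_scatter(records, model: DeathGater, ax=None):
    """Caspase-vs-PI scatter with thresholds and gate rays overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = _as_xy(records)
    labels = model.predict(xy)
    for mode in DEATH_MODES:
        sel = labels == mode
        if sel.any():
            ax.scatter(xy[sel, 0], xy[sel, 1], s=6, alpha=0.5,
                       color=_MODE_COLORS[mode], label=mode)
    tc, tp = model.t_caspase_, model.t_pi_
    hi = max(xy.max() * 1.05, tc * 2, tp * 2)
    ax.axvline(tc, color="k", lw=0.8, ls="--")
    ax.axhline(tp, color="k", lw=0.8, ls="--")
    for theta in (model.theta_necrotic_, model.theta_apoptotic_):
        r = np.radians(theta)
        ax.plot([tc, tc + hi * np.cos(r)], [tp, tp + hi * np.sin(r)],
                color="k", lw=0.8)
    ax.set_xlim(0, hi)
    ax.set_ylim(0, hi)
    ax.set_xlabel("mean Caspase 3/7 Green intensity")
    ax.set_ylabel("mean PI intensity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_death_fractions(death_counts: pd.DataFrame, ax=None):
    """Stacked bars of the four population fractions per well."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    bottom = np.zeros(len(death_counts))
    for mode in DEATH_MODES:
        vals = death_counts[f"frac_{mode}"].to_numpy(float)
        ax.bar(death_counts["well_id"], vals, bottom=bottom,
               color=_MODE_COLORS[mode], label=mode)
        bottom += vals
    ax.set_ylabel("fraction of nuclei")
    ax.legend(frameon=False, fontsize=8, ncol=2)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    return ax


def plot_dose_response(doses, viability, fit: DoseResponseFit | None = None, ax=None):
    """Normalized viability vs dose on a log axis, with the 4PL curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    doses = np.asarray(doses, dtype=float)
    ax.scatter(doses, viability, s=15, color="tab:blue")
    if fit is not None:
        grid = np.geomspace(doses[doses > 0].min() / 3, doses.max() * 3, 200)
        ax.plot(grid, fit.predict(grid), color="tab:orange",
                label=f"IC50 = {fit.ic50:.3g}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("dose")
    ax.set_ylabel("normalized viability")
    return ax
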