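"""Diagnostic plots: double-reciprocal, secondary and Delta replots.

Matplotlib is imported lazily so the analysis stack has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np

from .lineweaver import delta_replot
from .model import InhibitionResults


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_lineweaver_burk(results: InhibitionResults, ax=None):
    """1/v0 against 1/[S], one line per inhibitor level."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    df = results.model.data.mean_rates()
    for ln in results.lines:
        sub = df[df["I_mM"] == ln.I]
        x = 1.0 / sub["S_mM"].to_numpy()
        ax.plot(x, 1.0 / sub["v0"].to_numpy(), "o", ms=4, label=f"{ln.I:g} mM")
        grid = np.linspace(0, x.max(), 50)
        ax.plot(grid, ln.slope * grid + ln.intercept, "-", lw=1, color=ax.lines[-1].get_color())
    ax.set_xlabel("1/[S] (mM$^{-1}$)")
    ax.set_ylabel("1/$v_0$")
    ax.legend(title="[I]", fontsize=8)
    return ax


def plot_secondary(results: InhibitionResults, axes=None):
    """Apparent slope and intercept against [I] with the selected models."""
    plt = _mpl()
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    I = np.array([ln.I for ln in results.lines])
    grid = np.linspace(0, I.max() * 1.05, 200)
    for ax, attr, mdl, label in (
        (axes[0], "slope", results.profile.slope_model, "apparent $K_s/k_3$ (slope)"),
        (axes[1], "intercept", results.profile.intercept_model, "apparent $1/k_3$ (intercept)"),
    ):
        y = np.array([getattr(ln, attr) for ln in results.lines])
        ax.plot(I, y, "ko", ms=5)
        ax.plot(grid, mdl(grid), "-", lw=1)
        ax.set_xlabel("[I] (mM)")
        ax.set_ylabel(f"{label} [{mdl.form}]")
    return axes


def plot_delta_replot(results: InhibitionResults, which: str = "slope", ax=None):
    """1/Delta against 1/[I]; linear for the hyperbolic (partial) family."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    rep = delta_replot(list(results.lines), which=which)
    nz = [ln for ln in results.lines if ln.I > 0]
    x = 1.0 / np.array([ln.I for ln in nz])
    y = 1.0 / (np.array([getattr(ln, which) for ln in nz]) - rep.reference)
    ax.plot(x, y, "ko", ms=5)
    grid = np.linspace(0, x.max() * 1.05, 50)
    ax.plot(grid, rep.replot_slope * grid + rep.replot_intercept, "-", lw=1)
    ax.set_xlabel("1/[I] (mM$^{-1}$)")
    ax.set_ylabel(f"1/$\\Delta$ {which}")
    ax.set_title(f"$R^2$ = {rep.r2:.4f}")
    return ax
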