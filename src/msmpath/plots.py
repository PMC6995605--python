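"""Matplotlib renderings of the pipeline's standard diagnostics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_implied_timescales",
    "plot_ck_panels",
    "plot_free_energy_surface",
    "plot_dccm",
    "plot_pathway_network",
]


def plot_implied_timescales(its_table, path=None):
    """Implied timescales vs lag time, log-scaled, with the τ = t diagonal."""
    fig, ax = plt.subplots(figsize=(5, 4))
    lag = its_table["lag_time"].to_numpy()
    for col in [c for c in its_table.columns if c.startswith("t")]:
        ax.plot(lag, its_table[col].to_numpy(), "o-", label=col)
    ax.fill_between(lag, 0, lag, color="0.85")
    ax.plot(lag, lag, "k--", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("lag time")
    ax.set_ylabel("implied timescale")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ck_panels(report, path=None):
    """Estimated vs predicted staying probabilities, one panel per group."""
    n = len(report.set_labels)
    ncol = min(n, 3)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for a, label in enumerate(report.set_labels):
        ax = axes[a // ncol][a % ncol]
        ax.plot(report.steps, report.predicted[a], "b-", label="predicted")
        ax.errorbar(report.steps, report.estimated[a], yerr=report.std_err[a],
                    fmt="ko", ms=3, label="estimated")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"group {a}", fontsize=8)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_free_energy_surface(fes, path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    F = np.ma.masked_invalid(fes.free_energy)
    pcm = ax.pcolormesh(fes.x_edges, fes.y_edges, F.T, cmap="viridis")
    fig.colorbar(pcm, ax=ax, label="free energy (kT)")
    if fes.macrostate_locations is not None:
        for a, (x, y) in enumerate(fes.macrostate_locations):
            if np.isfinite(x):
                ax.annotate(f"S{a}", (x, y), color="w", fontsize=10, weight="bold",
                            ha="center", va="center")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dccm(dccm, path=None):
    """Diverging heatmap centered at 0 (blue = anti-correlated)."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    pcm = ax.imshow(dccm.values, cmap="bwr", vmin=-1, vmax=1, origin="lower")
    fig.colorbar(pcm, ax=ax, label=r"$C_{ij}$")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.set_title(dccm.subset, fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_pathway_network(macro_flux, populations, source, sink, path=None):
    """Macrostate network with edge widths proportional to net flux."""
    m = macro_flux.shape[0]
    theta = 2 * np.pi * np.arange(m) / m
    xy = np.c_[np.cos(theta), np.sin(theta)]
    fig, ax = plt.subplots(figsize=(5, 5))
    fmax = macro_flux.max() or 1.0
    for i in range(m):
        for j in range(m):
            if macro_flux[i, j] > 0:
                ax.annotate(
                    "", xy=xy[j], xytext=xy[i],
                    arrowprops=dict(arrowstyle="-|>", lw=4 * macro_flux[i, j] / fmax,
                                    color="tab:blue", shrinkA=18, shrinkB=18),
                )
    for a in range(m):
        name = "SA" if a == source else "SB" if a == sink else f"S{a}"
        ax.scatter(*xy[a], s=2500 * max(populations[a], 0.02), c="lightgray",
                   edgecolors="k", zorder=3)
        ax.annotate(name, xy[a], ha="center", va="center", zorder=4)
    ax.set_axis_off()
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
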