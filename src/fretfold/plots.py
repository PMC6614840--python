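"""Publication-style figures: FRET histograms, isotherms, TDPs, landscapes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fitting import HillFit, MixtureFit
from .kinetics import TransitionDensity
from .thermo import EnergyLandscape

__all__ = ["plot_fret_histogram", "plot_isotherm", "plot_tdp",
           "plot_landscape"]


def plot_fret_histogram(samples, mixture: MixtureFit | None = None,
                        bins: int = 40, path: str | Path | None = None,
                        title: str = ""):
    """Population histogram of per-molecule FRET values with mixture overlay."""
    fig, ax = plt.subplots(figsize=(4, 3))
    x = np.asarray(samples, float)
    ax.hist(x, bins=bins, range=(0, 1), density=True, alpha=0.6,
            color="0.6", edgecolor="0.3")
    if mixture is not None:
        grid = np.linspace(0, 1, 400)
        total = np.zeros_like(grid)
        for comp in mixture.components:
            pdf = comp.weight * np.exp(
                -0.5 * ((grid - comp.mean) / comp.sigma) ** 2
            ) / (comp.sigma * np.sqrt(2 * np.pi))
            ax.plot(grid, pdf, lw=1)
            total += pdf
        ax.plot(grid, total, "k-", lw=1.5)
    ax.set_xlabel(r"$E_{\mathrm{app}}$")
    ax.set_ylabel("probability density")
    if title:
        ax.set_title(title, fontsize=9)
    return _finish(fig, path)


def plot_isotherm(concentrations, responses, fit: HillFit | None = None,
                  xlabel: str = "ligand", path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.semilogx(concentrations, responses, "o", color="0.2")
    if fit is not None:
        c = np.asarray(concentrations, float)
        grid = np.geomspace(c[c > 0].min() / 3, c.max() * 3, 200)
        ax.semilogx(grid, fit.predict(grid), "-", color="tab:blue")
        ax.axvline(fit.K_D, ls=":", color="0.5")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("response")
    return _finish(fig, path)


def plot_tdp(tdp: TransitionDensity, path: str | Path | None = None):
    """Transition density on a logarithmic intensity scale."""
    from matplotlib.colors import LogNorm

    fig, ax = plt.subplots(figsize=(3.6, 3.2))
    counts = np.where(tdp.counts > 0, tdp.counts, np.nan)
    ax.pcolormesh(tdp.edges, tdp.edges, counts.T,
                  norm=LogNorm(vmin=1, vmax=max(tdp.counts.max(), 2)),
                  cmap="viridis")
    ax.plot([0, 1], [0, 1], "w--", lw=0.5)
    ax.set_xlabel(r"$E_{\mathrm{initial}}$")
    ax.set_ylabel(r"$E_{\mathrm{final}}$")
    return _finish(fig, path)


def plot_landscape(landscape: EnergyLandscape, order: list[str],
                   path: str | Path | None = None):
    """Schematic state free-energy diagram along a reaction coordinate."""
    fig, ax = plt.subplots(figsize=(4, 3))
    g = [0.0]
    for a, b in zip(order[:-1], order[1:]):
        g.append(g[-1] + landscape.delta_g0[(a, b)])
    xs = np.arange(len(order))
    for x, (gi, lbl) in enumerate(zip(g, order)):
        ax.hlines(gi, x - 0.3, x + 0.3, lw=3)
        ax.annotate(lbl, (x, gi), textcoords="offset points",
                    xytext=(0, 6), ha="center")
    ax.plot(xs, g, ":", color="0.6")
    ax.set_ylabel(r"$\Delta G^\circ$ (kcal/mol)")
    ax.set_xticks([])
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig
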