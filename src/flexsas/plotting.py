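"""Diagnostic plots for the standard solution-scattering analyses.

All functions take an optional matplotlib Axes and return it, so they
compose into multi-panel figures.
"""

from __future__ import annotations

import numpy as np

from .ensemble import EnsemblePool, EnsembleSelection, _fd_bins
from .sas import GuinierResults, PairDistribution, ScatteringCurve, kratky_dimensionless


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_curve(curve: ScatteringCurve, ax=None, label=None, **kwargs):
    """log I vs log q with error bars."""
    ax = _ax(ax)
    ax.errorbar(curve.q, curve.i, yerr=curve.sigma, fmt=".", ms=3,
                label=label, **kwargs)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$q$ ($\mathrm{\AA}^{-1}$)")
    ax.set_ylabel(r"$I(q)$")
    return ax


def plot_guinier(curve: ScatteringCurve, fit: GuinierResults, ax=None):
    """ln I vs q^2 with the fitted Guinier line and window."""
    ax = _ax(ax)
    lo, hi = fit.point_range
    q2 = curve.q ** 2
    pos = curve.i > 0
    ax.plot(q2[pos], np.log(curve.i[pos]), ".", ms=3, color="grey")
    win = slice(lo - 1, hi)
    ax.plot(q2[win], np.log(curve.i[win]), ".", ms=4, color="C0",
            label=f"fit window ({lo}-{hi})")
    xs = np.linspace(0.0, q2[hi - 1] * 1.2, 50)
    ax.plot(xs, np.log(fit.i0) - xs * fit.rg ** 2 / 3.0, "-", color="C3",
            label=f"$R_g$ = {fit.rg:.1f} $\\pm$ {fit.rg_err:.1f} $\\AA$")
    ax.set_xlabel(r"$q^2$ ($\mathrm{\AA}^{-2}$)")
    ax.set_ylabel(r"$\ln I$")
    ax.legend()
    return ax


def plot_kratky(curve: ScatteringCurve, fit: GuinierResults, ax=None,
                label=None):
    """Dimensionless Kratky plot with the globular reference point."""
    ax = _ax(ax)
    k = kratky_dimensionless(curve, fit)
    ax.plot(k["qrg"], k["value"], "-", lw=1, label=label)
    ax.plot(np.sqrt(3.0), 3.0 / np.e, "x", color="k", ms=8)
    ax.set_xlim(0, 8)
    ax.set_xlabel(r"$qR_g$")
    ax.set_ylabel(r"$(qR_g)^2\, I/I_0$")
    return ax


def plot_pr(pr: PairDistribution, ax=None, normalize=True, label=None):
    """P(r) with its Dmax marked."""
    ax = _ax(ax)
    y = pr.p / pr.p.max() if normalize and pr.p.max() > 0 else pr.p
    ax.plot(pr.r_grid, y, "-", label=label)
    ax.axvline(pr.dmax, ls=":", color="grey")
    ax.axhline(0.0, lw=0.5, color="k")
    ax.set_xlabel(r"$r$ ($\mathrm{\AA}$)")
    ax.set_ylabel(r"$P(r)$" + (" (norm.)" if normalize else ""))
    return ax


def plot_rg_distributions(pool: EnsemblePool, selection: EnsembleSelection,
                          ax=None):
    """Selected-ensemble vs starting-pool Rg histograms (shared binning)."""
    ax = _ax(ax)
    edges = _fd_bins(pool.rg_distribution)
    ax.hist(pool.rg_distribution, bins=edges, density=True, alpha=0.5,
            label="starting pool")
    ax.hist(selection.rg_distribution, bins=edges, density=True, alpha=0.5,
            label="selected ensemble")
    ax.set_xlabel(r"$R_g$ ($\mathrm{\AA}$)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
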