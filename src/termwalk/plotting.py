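"""Optional figure helpers (log-log scaling panels, IFS cloud).

Matplotlib is imported lazily; nothing in the analysis pipeline needs
these functions.
"""

from __future__ import annotations

import numpy as np

from ._fitting import ScalingFit
from .diffusion import MSDCurve
from .fluctuation import ACFCurve, IFSPointCloud, PowerSpectrum
from .heavytail import LogBinnedHistogram, PowerLawFit
from .structure import StructureFunctionSet

__all__ = [
    "plot_msd",
    "plot_structure_functions",
    "plot_zeta",
    "plot_spectrum",
    "plot_acf",
    "plot_ifs",
    "plot_tail",
]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def _overlay_fit(ax, x, fit: ScalingFit, sign: float = 1.0, label=None):
    lo, hi = fit.fit_window
    xs = np.geomspace(lo, hi, 50)
    ax.plot(xs, fit.prefactor * xs ** (sign * fit.exponent), "r-", lw=1.5, label=label)


def plot_msd(curve: MSDCurve, fit: ScalingFit | None = None, ax=None):
    ax = _ax(ax)
    ax.loglog(curve.delays, curve.msd, "o", ms=3, label="MSD")
    if fit is not None:
        _overlay_fit(ax, curve.delays, fit, label=f"slope {fit.exponent:.2f}")
    ax.set_xlabel(r"delay $\Delta$ (s)")
    ax.set_ylabel(r"MSD (mm$^2$)")
    ax.legend()
    return ax


def plot_structure_functions(sfs: StructureFunctionSet, max_q: float = 4, ax=None):
    """S_q(tau) panels; only orders up to max_q are drawn for clarity."""
    ax = _ax(ax)
    for i, qi in enumerate(sfs.q):
        if qi > max_q:
            continue
        ax.loglog(sfs.lags, sfs.S[i], "o-", ms=3, label=f"q={qi:g}")
        if sfs.zeta is not None:
            _overlay_fit(ax, sfs.lags.astype(float), sfs.zeta[i])
    ax.set_xlabel(r"lag $\tau$ (samples)")
    ax.set_ylabel(r"$S_q(\tau)$")
    ax.legend()
    return ax


def plot_zeta(sfs: StructureFunctionSet, ax=None):
    ax = _ax(ax)
    zeta = sfs.zeta_values()
    ax.plot(sfs.q, zeta, "o", label=r"$\zeta(q)$")
    if sfs.H is not None:
        qs = np.linspace(0, sfs.q.max(), 20)
        intercept = zeta.mean() - sfs.H * sfs.q.mean()
        ax.plot(qs, sfs.H * qs + intercept, "r-", label=f"H={sfs.H:.2f}")
    ax.set_xlabel("q")
    ax.set_ylabel(r"$\zeta(q)$")
    ax.legend()
    return ax


def plot_spectrum(spec: PowerSpectrum, ax=None):
    ax = _ax(ax)
    ax.loglog(spec.frequencies, spec.power, lw=0.7)
    if spec.beta is not None:
        _overlay_fit(ax, spec.frequencies, spec.beta, sign=-1.0,
                     label=rf"$\beta$={spec.beta.exponent:.2f}")
        ax.legend()
    ax.set_xlabel("frequency (1/sample)")
    ax.set_ylabel("power")
    return ax


def plot_acf(acf: ACFCurve, fit: ScalingFit | None = None, ax=None):
    ax = _ax(ax)
    pos = acf.C[1:] > 0
    ax.loglog(acf.lags[1:][pos], acf.C[1:][pos], "o", ms=3, label="C(tau)")
    if fit is not None:
        _overlay_fit(ax, acf.lags[1:].astype(float), fit, sign=-1.0,
                     label=rf"$\gamma$={fit.exponent:.2f}")
    ax.set_xlabel(r"lag $\tau$ (samples)")
    ax.set_ylabel(r"$C(\tau)$")
    ax.legend()
    return ax


def plot_ifs(cloud: IFSPointCloud, ax=None):
    ax = _ax(ax)
    ax.plot(cloud.points[:, 0], cloud.points[:, 1], ",", color="k")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_aspect("equal")
    return ax


def plot_tail(hist: LogBinnedHistogram, fit: PowerLawFit | None = None, ax=None):
    ax = _ax(ax)
    pos = hist.density > 0
    ax.loglog(hist.centers[pos], hist.density[pos], "o", ms=4, label="data")
    if fit is not None:
        xs = np.geomspace(fit.x_min, hist.edges[-1], 50)
        # anchor the model line at the density near x_min
        i0 = np.searchsorted(hist.centers, fit.x_min)
        i0 = min(max(i0, 0), pos.sum() - 1)
        anchor = hist.density[pos][i0] if pos.any() else 1.0
        ax.plot(xs, anchor * (xs / xs[0]) ** (-fit.exponent), "r-",
                label=f"slope -{fit.exponent:.2f}")
    ax.set_xlabel("value")
    ax.set_ylabel("density")
    ax.legend()
    return ax
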