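"""Shared log-log power-law regression.

Every scaling estimate in the package (MSD exponent, zeta(q), spectral
slope, ACF decay) reduces to an ordinary least-squares line on
log10(y) vs log10(x) over a stated abscissa window.  The fit result is
carried around as a :class:`ScalingFit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ScalingFit", "fit_loglog"]


@dataclass(frozen=True)
class ScalingFit:
    """A fitted power law y = prefactor * x**exponent.

    Attributes
    ----------
    exponent : float
        Log-log slope.
    prefactor : float
        10**intercept of the log-log line (e.g. a diffusion coefficient).
    stderr : float
        Standard error of the slope.
    fit_window : tuple of float
        (min, max) of the abscissa values actually used.
    r_squared : float
        Coefficient of determination of the log-log line.
    n_points : int
        Number of points used.
    """

    exponent: float
    prefactor: float
    stderr: float
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int


def fit_loglog(x, y, window=None, min_points: int = 2) -> ScalingFit:
    """Least-squares line on log10(y) vs log10(x).

    Parameters
    ----------
    x, y : array-like
        Abscissa and ordinate; only pairs with x > 0 and y > 0 enter the
        fit (non-positive ordinates cannot be logged and are dropped).
    window : (float, float), optional
        Inclusive abscissa window; ``None`` uses the full range.
    min_points : int
        Minimum number of usable points; fewer raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    mask = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    if window is not None:
        lo, hi = window
        if not lo < hi:
            raise ValueError(f"invalid window {window!r}")
        mask &= (x >= lo) & (x <= hi)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} usable points in window "
            f"(need at least {min_points})"
        )
    lx, ly = np.log10(x[mask]), np.log10(y[mask])
    res = stats.linregress(lx, ly)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return ScalingFit(
        exponent=float(res.slope),
        prefactor=float(10.0**res.intercept),
        stderr=stderr,
        fit_window=(float(x[mask].min()), float(x[mask].max())),
        r_squared=r2,
        n_points=int(mask.sum()),
    )
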