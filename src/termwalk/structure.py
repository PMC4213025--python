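"""Kolmogorov q-order structure functions and zeta(q) scaling.

The structure function of order q at lag tau is the q-th absolute
moment of increments, S_q(tau) = <|delta(tau)|^q>.  When S_q scales as
tau**zeta(q), the exponents zeta(q) versus q form (for self-affine
series) a line of slope H; H = 1/2 marks normal diffusion and
1/2 < H <= 1 superdiffusion.  For a Levy walk the slope is related to
the Levy exponent by mu = 1 + 1/H, giving a second, independent route
to mu besides the MSD.

Two increment constructions are provided:

* :func:`structure_functions` — increments of an arbitrary scalar
  series, delta(tau) = x(t+tau) - x(t);
* :func:`trajectory_structure_functions` — coarse-grained traveled
  distances of a planar track, delta(tau) = |r(t+tau) - r(t)|, the
  construction under which zeta(2) equals the MSD exponent.  This is
  the one the analysis pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._fitting import ScalingFit, fit_loglog
from .trajectory import StepSeries, Trajectory

__all__ = [
    "StructureFunctionSet",
    "default_lags",
    "structure_functions",
    "trajectory_structure_functions",
    "fit_zeta",
    "H_and_mu",
    "classify_H",
]

DEFAULT_Q = tuple(range(1, 9))


@dataclass
class StructureFunctionSet:
    """S_q(tau) matrix with (optionally) fitted zeta(q), H and mu_q.

    ``S[i, j]`` is the order ``q[i]`` structure function at lag
    ``lags[j]`` (lags in samples).  ``zeta`` holds one ScalingFit per q
    after :func:`fit_zeta`; ``H``/``mu_q`` are filled by
    :func:`H_and_mu`.
    """

    q: np.ndarray
    lags: np.ndarray
    S: np.ndarray
    dt: float = 1.0
    zeta: list[ScalingFit] | None = None
    H: float | None = None
    H_stderr: float | None = None
    mu_q: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.q), len(self.lags)):
            raise ValueError("S must have shape (len(q), len(lags))")
        if np.any(self.S < 0):
            raise ValueError("structure functions are non-negative")

    def zeta_values(self) -> np.ndarray:
        if self.zeta is None:
            raise ValueError("zeta not fitted yet; call fit_zeta first")
        return np.array([f.exponent for f in self.zeta])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.S.T, columns=[f"S_q{qi:g}" for qi in self.q])
        df.insert(0, "lag", self.lags)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_lags(n: int, per_decade: int = 20, max_fraction: float = 0.1) -> np.ndarray:
    """Log-spaced integer lags, 20/decade, from 1 to max_fraction*n."""
    max_lag = int(np.floor(max_fraction * n))
    if max_lag < 1:
        raise ValueError("series too short")
    decades = np.log10(max_lag) if max_lag > 1 else 0.0
    n_pts = max(int(np.ceil(decades * per_decade)) + 1, 1)
    return np.unique(np.round(np.geomspace(1, max_lag, n_pts)).astype(int))


def _moments(abs_inc: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Mean of |increment|**q for each q, reusing integer-power products."""
    out = np.empty(len(q))
    int_q = np.all(q == np.round(q)) and np.all(np.diff(q) > 0)
    if int_q:
        acc = np.ones_like(abs_inc)
        power = 0
        for i, qi in enumerate(np.round(q).astype(int)):
            while power < qi:
                acc = acc * abs_inc
                power += 1
            out[i] = acc.mean()
    else:
        for i, qi in enumerate(q):
            out[i] = np.mean(abs_inc**qi)
    return out


def structure_functions(
    series, q=DEFAULT_Q, lags=None, dt: float = 1.0
) -> StructureFunctionSet:
    """S_q(tau) = <|x(t+tau) - x(t)|^q> for a scalar series.

    ``series`` may be a plain array or a :class:`StepSeries` (its
    per-interval lengths are used).  Averages run over all overlapping
    origins t.  Lags default to log-spaced integers up to a tenth of
    the series length.
    """
    if isinstance(series, StepSeries):
        dt = series.dt
        series = series.lengths
    x = np.asarray(series, dtype=float)
    q = np.asarray(q, dtype=float)
    if lags is None:
        lags = default_lags(len(x))
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1) or np.any(lags >= len(x)):
        raise ValueError("lags must satisfy 1 <= lag < series length")
    S = np.empty((len(q), len(lags)))
    for j, tau in enumerate(lags):
        S[:, j] = _moments(np.abs(x[tau:] - x[:-tau]), q)
    return StructureFunctionSet(q=q, lags=lags, S=S, dt=dt)


def trajectory_structure_functions(
    traj: Trajectory, q=DEFAULT_Q, lags=None
) -> StructureFunctionSet:
    """S_q(tau) = <|r(t+tau) - r(t)|^q> for a planar trajectory.

    The increment at lag tau is the straight-line distance between
    positions tau samples apart — the traveled distance coarse-grained
    at scale tau.  zeta(2) of this set is the MSD exponent.
    """
    q = np.asarray(q, dtype=float)
    if lags is None:
        lags = default_lags(traj.n_samples)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1) or np.any(lags >= traj.n_samples):
        raise ValueError("lags must satisfy 1 <= lag < number of samples")
    S = np.empty((len(q), len(lags)))
    for j, tau in enumerate(lags):
        d = np.hypot(traj.x[tau:] - traj.x[:-tau], traj.y[tau:] - traj.y[:-tau])
        S[:, j] = _moments(d, q)
    return StructureFunctionSet(q=q, lags=lags, S=S, dt=traj.dt)


def fit_zeta(
    sfs: StructureFunctionSet,
    window: tuple[float, float] | None = None,
    min_points: int = 5,
) -> StructureFunctionSet:
    """Fit zeta(q): the log-log slope of S_q versus lag, per q.

    Lags with non-positive S_q (log undefined) are dropped; if fewer
    than ``min_points`` usable lags remain for some q, the fit errors.
    Returns a new set with ``zeta`` filled.
    """
    fits = [
        fit_loglog(sfs.lags.astype(float), sfs.S[i], window=window, min_points=min_points)
        for i in range(len(sfs.q))
    ]
    return replace(sfs, zeta=fits)


def H_and_mu(sfs: StructureFunctionSet) -> tuple[float, float]:
    """Slope H of zeta(q) vs q and the Levy exponent mu_q = 1 + 1/H.

    H is the least-squares slope with a free intercept (the intercept
    is near zero for clean self-affine scaling and is retained in the
    set's ``H_stderr`` companion fit).  H = 1/2 marks normal diffusion;
    1/2 < H <= 1 is the superdiffusive band.  Requires zeta for at
    least 3 q values; H <= 0 is an error.  The set is updated in place
    and (H, mu_q) returned.
    """
    if sfs.zeta is None:
        raise ValueError("call fit_zeta before H_and_mu")
    if len(sfs.q) < 3:
        raise ValueError("need zeta(q) for at least 3 q values")
    zeta = sfs.zeta_values()
    res = stats.linregress(sfs.q, zeta)
    H = float(res.slope)
    if H <= 0:
        raise ValueError(f"non-positive zeta(q) slope H={H:g}")
    sfs.H = H
    sfs.H_stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    sfs.mu_q = 1.0 + 1.0 / H
    return H, sfs.mu_q


def classify_H(H: float, tol: float = 0.02) -> str:
    """'normal' (H~1/2), 'superdiffusive' (1/2<H<=1) or 'other'."""
    if abs(H - 0.5) <= tol:
        return "normal"
    if 0.5 < H <= 1.0 + tol:
        return "superdiffusive"
    return "other"
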