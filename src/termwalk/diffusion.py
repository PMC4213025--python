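"""Mean-squared displacement and the anomalous-diffusion exponent.

The time-averaged MSD of a track, msd(D) = <|r(t+D) - r(t)|^2>_t, grows
as D**alpha; alpha = 1 is normal (Brownian) diffusion, alpha > 1
superdiffusion, alpha = 2 the ballistic bound for a walker with finite
speed.  For a superdiffusive Levy walk the MSD exponent and the
step-length (move-duration) Levy exponent mu are tied by mu = 4 - alpha
in the regime 1 <= alpha <= 2 (2 <= mu <= 3), which lets a Levy
exponent be read off a diffusion measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fitting import ScalingFit, fit_loglog
from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "ScalingFit",
    "default_delays",
    "msd",
    "fit_anomalous_exponent",
    "classify_diffusion",
    "mu_from_alpha",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD sampled at a set of delays.

    ``delays`` are in seconds (strictly increasing multiples of dt),
    ``msd`` in mm**2, ``n_pairs`` counts the (t, t+delay) pairs averaged
    at each delay.  ``dt`` and ``duration`` of the source track are kept
    for window defaults.
    """

    delays: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    dt: float
    duration: float

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delay_s": self.delays, "msd_mm2": self.msd, "n_pairs": self.n_pairs}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_delays(
    traj: Trajectory,
    points_per_decade: int = 25,
    max_fraction: float = 0.05,
    min_lag: int = 1,
) -> np.ndarray:
    """Log-spaced delay grid: multiples of dt up to max_fraction*duration.

    25 points per decade by default; the grid stops at 5% of the track
    duration because confined tracks saturate (and the statistics decay)
    at large delays.
    """
    n = traj.n_samples
    max_lag = int(np.floor(max_fraction * (n - 1)))
    max_lag = max(max_lag, min_lag)
    if max_lag < min_lag:
        raise ValueError("track too short for the requested delay grid")
    decades = np.log10(max_lag / min_lag) if max_lag > min_lag else 0.0
    n_pts = max(int(np.ceil(decades * points_per_decade)) + 1, 1)
    lags = np.unique(
        np.round(np.geomspace(min_lag, max_lag, n_pts)).astype(int)
    )
    return lags * traj.dt


def msd(traj: Trajectory, delays) -> MSDCurve:
    """Time-averaged MSD over all sliding origins.

    msd(D) = mean over t of |r(t+D) - r(t)|**2, using every available
    (overlapping) pair.  Each delay must be a positive multiple of dt
    and smaller than the track duration.
    """
    delays = np.atleast_1d(np.asarray(delays, dtype=float))
    dt = traj.dt
    lags = delays / dt
    lags_int = np.round(lags).astype(int)
    if np.any(np.abs(lags - lags_int) > 1e-9 * np.maximum(lags, 1.0)) or np.any(
        lags_int < 1
    ):
        raise ValueError("each delay must be a positive multiple of dt")
    if np.any(lags_int > traj.n_samples - 1):
        raise ValueError("delays must not exceed the track duration")
    out = np.empty(len(lags_int))
    n_pairs = np.empty(len(lags_int), dtype=int)
    for j, k in enumerate(lags_int):
        dx = traj.x[k:] - traj.x[:-k]
        dy = traj.y[k:] - traj.y[:-k]
        out[j] = np.mean(dx * dx + dy * dy)
        n_pairs[j] = len(dx)
    return MSDCurve(
        delays=delays, msd=out, n_pairs=n_pairs, dt=dt, duration=traj.duration
    )


def fit_anomalous_exponent(
    curve: MSDCurve, window: tuple[float, float] | None = None
) -> ScalingFit:
    """Fit msd ~ D**alpha on log-log axes inside a delay window.

    The default window spans 2*dt to 5% of the track duration, avoiding
    both single-interval discreteness and the large-delay saturation of
    confined tracks.  The returned ``prefactor`` plays the role of a
    (generalized) diffusion coefficient.  At least 5 delay points must
    fall inside the window.
    """
    if window is None:
        window = (2.0 * curve.dt, 0.05 * curve.duration)
    return fit_loglog(curve.delays, curve.msd, window=window, min_points=5)


def classify_diffusion(alpha: float, tol: float = 0.05) -> str:
    """'subdiffusive' (alpha<1), 'normal' (alpha~1) or 'superdiffusive'."""
    if alpha < 1.0 - tol:
        return "subdiffusive"
    if alpha <= 1.0 + tol:
        return "normal"
    return "superdiffusive"


def mu_from_alpha(alpha: float) -> float:
    """Levy exponent from the MSD exponent: mu = 4 - alpha.

    Valid for superdiffusive walks with 1 <= alpha <= 2 (2 <= mu <= 3).
    Outside that band the value is still returned but a warning flags
    the extrapolation.
    """
    if not 1.0 <= alpha <= 2.0:
        warnings.warn(
            f"alpha={alpha:g} lies outside [1, 2]; mu = 4 - alpha is an "
            "extrapolation beyond the superdiffusive Levy-walk regime",
            stacklevel=2,
        )
    return 4.0 - alpha
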