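"""Spectral, autocorrelation and chaos-game views of a step series.

Three complementary probes of temporal structure in the per-interval
traveled-distance series l(t):

* the FFT periodogram, whose log-log slope -beta classifies the series
  as white (beta=0), pink (beta=1) or brown (beta=2) noise;
* the autocorrelation function C(tau), whose power-law decay
  C ~ tau**(-gamma) with 0 < gamma < 1 signals long memory;
* the iterated-function-system (chaos game) map, which renders
  temporal correlation structure as spatial self-similarity in the
  unit square by iterating half-way moves toward quartile-assigned
  corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from ._fitting import ScalingFit, fit_loglog
from .trajectory import StepSeries

__all__ = [
    "PowerSpectrum",
    "ACFCurve",
    "IFSPointCloud",
    "power_spectrum",
    "autocorrelation",
    "fit_acf_decay",
    "classify_acf_decay",
    "ifs_map",
    "ifs_occupancy",
]


def _as_array(series) -> np.ndarray:
    if isinstance(series, StepSeries):
        return np.asarray(series.lengths, dtype=float)
    return np.asarray(series, dtype=float)


@dataclass
class PowerSpectrum:
    """One-sided averaged periodogram with a fitted spectral slope.

    ``frequencies`` are in cycles per sample, in (0, 0.5]; ``power`` is
    normalized so that its sum equals the series variance (Parseval).
    ``beta`` stores the fitted spectral exponent of S(f) ~ 1/f**beta
    (the *negated* log-log slope) as a ScalingFit whose ``exponent``
    field is beta itself.
    """

    frequencies: np.ndarray
    power: np.ndarray
    segment_length: int
    n_segments: int
    beta: ScalingFit | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(self.frequencies <= 0) or np.any(self.frequencies > 0.5 + 1e-12):
            raise ValueError("frequencies must lie in (0, Nyquist]")


@dataclass
class ACFCurve:
    """Autocorrelation C(tau) for tau = 0..max_lag, with C(0) = 1."""

    lags: np.ndarray
    C: np.ndarray
    gamma: ScalingFit | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.C = np.asarray(self.C, dtype=float)
        if not np.isclose(self.C[0], 1.0):
            raise ValueError("C(0) must equal 1")


@dataclass
class IFSPointCloud:
    """Chaos-game iterates in the unit square.

    ``points[k]`` is the position after consuming series value k;
    ``quartiles`` are the three bin edges used for corner assignment.
    """

    points: np.ndarray
    quartiles: np.ndarray
    n_points: int


def power_spectrum(
    series,
    segment_length: int = 4096,
    window: str = "boxcar",
    fit_band: tuple[float, float] | None = None,
) -> PowerSpectrum:
    """Averaged FFT periodogram of consecutive segments, with slope fit.

    Each length-L segment is mean-removed (plain FFT periodogram;
    ``window='hann'`` applies a Hann taper instead) and its one-sided
    periodogram computed with the normalization sum(power) = variance.
    All full segments are averaged.  The spectral exponent beta is the
    negated log-log slope over ``fit_band`` (default [4/L, Nyquist/4],
    avoiding the DC edge and aliasing corner).
    """
    x = _as_array(series)
    L = int(segment_length)
    if len(x) < L:
        raise ValueError(f"series length {len(x)} < segment_length {L}")
    if window not in ("boxcar", "hann"):
        raise ValueError("window must be 'boxcar' or 'hann'")
    n_seg = len(x) // L
    taper = np.hanning(L) if window == "hann" else np.ones(L)
    norm = np.sum(taper**2)
    acc = None
    for s in range(n_seg):
        seg = x[s * L : (s + 1) * L]
        seg = (seg - seg.mean()) * taper
        X = np.fft.rfft(seg)
        p = np.abs(X) ** 2 / (L * norm)
        p[1:] *= 2.0
        if L % 2 == 0:
            p[-1] /= 2.0
        acc = p if acc is None else acc + p
    power = acc[1:] / n_seg  # drop DC
    freqs = np.fft.rfftfreq(L)[1:]
    spec = PowerSpectrum(
        frequencies=freqs, power=power, segment_length=L, n_segments=n_seg
    )
    if fit_band is None:
        fit_band = (4.0 / L, 0.5 / 4.0)
    fit = fit_loglog(freqs, power, window=fit_band, min_points=5)
    spec.beta = ScalingFit(
        exponent=-fit.exponent,
        prefactor=fit.prefactor,
        stderr=fit.stderr,
        fit_window=fit.fit_window,
        r_squared=fit.r_squared,
        n_points=fit.n_points,
    )
    return spec


def autocorrelation(series, max_lag: int) -> ACFCurve:
    """C(tau) = [1/((N-tau) sigma^2)] sum_t (l_t - <l>)(l_{t+tau} - <l>).

    The variance sigma^2 and mean <l> are those of the full series
    (population normalization), so C(0) = 1 exactly.  Requires
    max_lag < N/2 and a non-degenerate series.
    """
    x = _as_array(series)
    N = len(x)
    if not 1 <= max_lag < N / 2:
        raise ValueError("max_lag must satisfy 1 <= max_lag < N/2")
    mean = x.mean()
    dev = x - mean
    var = float(np.mean(dev**2))
    if var == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    C = np.empty(max_lag + 1)
    C[0] = 1.0
    for tau in range(1, max_lag + 1):
        C[tau] = float(dev[:-tau] @ dev[tau:]) / ((N - tau) * var)
    return ACFCurve(lags=np.arange(max_lag + 1), C=C)


def fit_acf_decay(
    acf: ACFCurve, window: tuple[float, float] | None = None, min_points: int = 3
) -> ScalingFit:
    """Power-law decay exponent gamma of C(tau) ~ tau**(-gamma).

    Only lags >= 1 with C(tau) > 0 enter the fit (non-positive values
    cannot be logged and are dropped); too few surviving lags raises.
    The returned ScalingFit's ``exponent`` is gamma (positive for a
    decaying ACF); 0 < gamma < 1 with a good r^2 indicates long memory.
    """
    lags = acf.lags[1:].astype(float)
    C = acf.C[1:]
    fit = fit_loglog(lags, C, window=window, min_points=min_points)
    return ScalingFit(
        exponent=-fit.exponent,
        prefactor=fit.prefactor,
        stderr=fit.stderr,
        fit_window=fit.fit_window,
        r_squared=fit.r_squared,
        n_points=fit.n_points,
    )


def classify_acf_decay(fit: ScalingFit, r2_threshold: float = 0.95) -> str:
    """'long-memory' for 0 < gamma < 1 with a convincing power-law fit."""
    if fit.r_squared < r2_threshold:
        return "poor power-law fit"
    if 0.0 < fit.exponent < 1.0:
        return "long-memory"
    return "short-range"


_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def ifs_map(series) -> IFSPointCloud:
    """Chaos-game (IFS) representation of a scalar series.

    Values are binned into four classes by the series' quartiles
    (x < q1 -> corner (0,0); q1 <= x < q2 -> (1,0); q2 <= x < q3 ->
    (0,1); x >= q3 -> (1,1)) and the map p_{n+1} = (p_n + corner_n)/2
    is iterated from p_0 = (0.5, 0.5).  All iterates lie in the unit
    square; self-similar (correlated) series leave characteristic
    fractal voids, iid series fill the square uniformly.
    """
    x = _as_array(series)
    if len(x) < 4:
        raise ValueError("need at least 4 values for quartile binning")
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    if not q3 > q1:
        raise ValueError("degenerate quartiles: series is (nearly) constant")
    bins = np.digitize(x, [q1, q2, q3])  # 0..3, x >= q3 -> 3
    corners = _CORNERS[bins]
    # p[t] = 0.5*corner[t] + 0.5*p[t-1], p[-1] = (0.5, 0.5)
    zi = np.array([0.25])
    u, _ = lfilter([0.5], [1.0, -0.5], corners[:, 0], zi=zi)
    v, _ = lfilter([0.5], [1.0, -0.5], corners[:, 1], zi=zi)
    return IFSPointCloud(
        points=np.column_stack([u, v]),
        quartiles=np.array([q1, q2, q3]),
        n_points=len(x),
    )


def ifs_occupancy(cloud: IFSPointCloud, grid: int = 16) -> float:
    """Fraction of cells of a grid x grid partition visited by the cloud.

    Near 1 for iid input (the chaos game then fills the square); well
    below 1 for series with long-memory structure.
    """
    ij = np.clip((cloud.points * grid).astype(int), 0, grid - 1)
    occupied = np.unique(ij[:, 0] * grid + ij[:, 1]).size
    return occupied / grid**2
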