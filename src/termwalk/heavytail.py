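"""Log-binned histograms and maximum-likelihood power-law tail fits.

Step lengths and waiting-bout durations are tested for heavy tails
with the continuous maximum-likelihood estimator

    alpha_hat = 1 + n / sum(ln(x_i / x_min)),   x_i >= x_min,

and, when ``x_min`` is not fixed a priori, the lower cutoff is chosen
by minimizing the Kolmogorov-Smirnov distance between the empirical
tail and the fitted power-law CDF (the standard Clauset-Shalizi-Newman
procedure).  Log-binned histograms are provided for visual comparison;
they are descriptive, never the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import WaitBout

__all__ = [
    "PowerLawFit",
    "LogBinnedHistogram",
    "log_binned_histogram",
    "mle_powerlaw",
    "fit_waiting_times",
]


@dataclass(frozen=True)
class PowerLawFit:
    """MLE power-law tail fit P(x) ~ x**(-exponent) for x >= x_min.

    ``n_tail`` counts the points at or above ``x_min``;
    ``ks_distance`` is the KS statistic between the tail's empirical
    CDF and the fitted model; ``stderr`` is the asymptotic
    (alpha-1)/sqrt(n_tail) unless a bootstrap was requested; ``method``
    records whether x_min was fixed or scanned.
    """

    exponent: float
    x_min: float
    n_tail: int
    ks_distance: float
    stderr: float
    method: str

    def __post_init__(self) -> None:
        if self.exponent <= 1:
            raise ValueError("a normalizable power law needs exponent > 1")
        if not 0.0 <= self.ks_distance <= 1.0:
            raise ValueError("KS distance must lie in [0, 1]")


@dataclass
class LogBinnedHistogram:
    """Geometric-bin histogram normalized to unit integral."""

    edges: np.ndarray
    centers: np.ndarray
    density: np.ndarray
    counts: np.ndarray

    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "center": self.centers,
                "density": self.density,
                "count": self.counts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def log_binned_histogram(data, bins_per_decade: int = 10) -> LogBinnedHistogram:
    """Histogram on geometric bins; density = count / (n * bin width).

    Bin centers are geometric midpoints and zero-count bins are kept so
    that the log-log profile shows gaps honestly.  All data must be
    positive; at least 10 points are required.
    """
    x = np.asarray(data, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 data points")
    if np.any(x <= 0):
        raise ValueError("log binning requires strictly positive data")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        hi = lo * 10 ** (1.0 / bins_per_decade)
    n_bins = max(int(np.ceil(np.log10(hi / lo) * bins_per_decade)), 1)
    edges = lo * 10 ** (np.arange(n_bins + 1) / bins_per_decade)
    edges[-1] = max(edges[-1], hi * (1 + 1e-12))
    counts, _ = np.histogram(x, bins=edges)
    density = counts / (len(x) * np.diff(edges))
    centers = np.sqrt(edges[:-1] * edges[1:])
    return LogBinnedHistogram(
        edges=edges, centers=centers, density=density, counts=counts
    )


def _tail_fit(xs_sorted: np.ndarray, x_min: float) -> tuple[float, int, float]:
    """(alpha, n_tail, ks) for the tail of an ascending-sorted sample."""
    i0 = int(np.searchsorted(xs_sorted, x_min, side="left"))
    tail = xs_sorted[i0:]
    n = len(tail)
    if n < 10:
        raise ValueError(f"only {n} tail points at or above x_min={x_min:g} (need 10)")
    log_sum = float(np.sum(np.log(tail / x_min)))
    if log_sum == 0.0:
        raise ValueError("all tail values equal x_min; MLE diverges")
    alpha = 1.0 + n / log_sum
    model = 1.0 - (tail / x_min) ** (1.0 - alpha)
    i = np.arange(n)
    ks = float(np.max(np.maximum(np.abs(model - i / n), np.abs(model - (i + 1) / n))))
    return alpha, n, ks


def _scan_candidates(
    xs_sorted: np.ndarray, floor: float, min_tail: int, max_candidates: int = 100
):
    """Unique candidate cutoffs leaving >= min_tail points, thinned log-evenly."""
    upper = xs_sorted[-min_tail]
    cands = np.unique(xs_sorted[(xs_sorted >= floor) & (xs_sorted <= upper)])
    if len(cands) == 0:
        raise ValueError("no admissible x_min candidates")
    if len(cands) > max_candidates:
        targets = np.geomspace(cands[0], cands[-1], max_candidates)
        idx = np.unique(np.searchsorted(cands, targets, side="left").clip(0, len(cands) - 1))
        cands = cands[idx]
    return cands


def mle_powerlaw(
    data,
    x_min="scan",
    n_bootstrap: int = 0,
    seed: int = 0,
    min_x_min: float | None = None,
    min_tail: int | None = None,
) -> PowerLawFit:
    """Continuous MLE power-law fit with fixed or scanned x_min.

    With a numeric ``x_min`` the estimator is closed-form.  With
    ``x_min='scan'`` every (thinned) distinct data value is tried and
    the cutoff minimizing the KS distance between tail and model is
    kept.  ``min_x_min`` restricts the scan floor (used for waiting
    times, where cutoffs below the sampling interval are meaningless).
    ``min_tail`` is the smallest tail the scan may select (default
    max(10, sqrt(n)): allowing arbitrarily small tails lets the scan
    latch onto a handful of extreme points of data that have no
    power-law tail at all, e.g. speed-capped step lengths).
    ``n_bootstrap > 0`` replaces the asymptotic standard error with a
    seeded nonparametric bootstrap at the chosen cutoff.
    """
    xs = np.sort(np.asarray(data, dtype=float))
    if len(xs) < 10:
        raise ValueError("need at least 10 data points")
    if np.any(xs <= 0):
        raise ValueError("power-law fitting requires positive data")

    if isinstance(x_min, str):
        if x_min != "scan":
            raise ValueError("x_min must be a number or 'scan'")
        if min_tail is None:
            min_tail = max(10, int(np.sqrt(len(xs))))
        min_tail = min(min_tail, len(xs))
        floor = xs[0] if min_x_min is None else max(min_x_min, xs[0])
        best = None
        for cand in _scan_candidates(xs, floor, min_tail):
            # a tail must span some dynamic range to constrain a slope;
            # atoms (grid or speed-cap artifacts) otherwise "fit" alpha=inf
            if xs[-1] < 2.0 * cand:
                continue
            try:
                alpha, n, ks = _tail_fit(xs, float(cand))
            except ValueError:
                continue
            if n < min_tail:
                continue
            if best is None or ks < best[3]:
                best = (alpha, float(cand), n, ks)
        if best is None:
            raise ValueError("no candidate x_min admitted a fit")
        alpha, chosen, n_tail, ks = best
        method = "scan_xmin"
    else:
        chosen = float(x_min)
        if min_x_min is not None and chosen < min_x_min - 1e-12:
            raise ValueError(f"x_min={chosen:g} below the admissible minimum {min_x_min:g}")
        alpha, n_tail, ks = _tail_fit(xs, chosen)
        method = "fixed_xmin"

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_bootstrap):
            resampled = np.sort(rng.choice(xs, size=len(xs), replace=True))
            try:
                a, _, _ = _tail_fit(resampled, chosen)
            except ValueError:
                continue
            reps.append(a)
        stderr = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
    else:
        stderr = (alpha - 1.0) / np.sqrt(n_tail)

    return PowerLawFit(
        exponent=float(alpha),
        x_min=chosen,
        n_tail=int(n_tail),
        ks_distance=float(ks),
        stderr=float(stderr),
        method=method,
    )


def fit_waiting_times(
    waits: list[WaitBout], x_min="scan", n_bootstrap: int = 0, seed: int = 0
) -> PowerLawFit:
    """Power-law MLE on waiting-bout durations.

    Durations are discrete multiples of the sampling interval dt; the
    continuous estimator is applied to them with the admissible cutoff
    floored at dt (cutting below one sampling interval is meaningless,
    and x_min >= 2*dt is advisable when dt-discreteness is severe).
    Requires at least 10 bouts.
    """
    if len(waits) < 10:
        raise ValueError(f"need at least 10 bouts, got {len(waits)}")
    durations = np.array([w.duration for w in waits], dtype=float)
    dt = min(w.duration / w.n_samples for w in waits)
    return mle_powerlaw(
        durations, x_min=x_min, n_bootstrap=n_bootstrap, seed=seed, min_x_min=dt
    )
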