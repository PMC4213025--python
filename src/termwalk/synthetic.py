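"""Synthetic walkers and noise series with known scaling exponents.

Every estimator in the package is verifiable by parameter recovery on
the generators here, without any external data:

* ``powerlaw_variates`` — inverse-transform power-law random numbers
  (the standard transformation between a uniform variate and a
  Pareto-tailed one).
* ``simulate_walker`` — a constant-speed Levy *walk* (power-law move
  durations, hence heavy-tailed segment lengths), a Brownian walker, or
  a ballistic control, optionally confined to a circular arena with
  specular reflection or wall-following at the boundary, and optionally
  interleaved with power-law waiting bouts.
* ``relaxation_series`` — AR(1) relaxation return map
  x_{t+1} = lambda*x_t + xi_t with standard-normal innovations.
* ``spectral_noise`` — colored noise with a prescribed 1/f**beta
  power spectrum (white beta=0, pink beta=1, brown beta=2).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "SimConfig",
    "powerlaw_variates",
    "simulate_walker",
    "relaxation_series",
    "spectral_noise",
]

MODELS = ("levy_walk", "brownian", "ballistic")
BOUNDARIES = ("none", "reflect", "follow")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def powerlaw_variates(alpha: float, x_min: float, n: int, seed=0) -> np.ndarray:
    """Continuous power-law variates P(x) ~ x**(-alpha) for x >= x_min.

    Uses the inverse-transform x = x_min * (1 - r)**(-1/(alpha - 1))
    with r uniform on [0, 1); requires alpha > 1 for a normalizable
    tail.  ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if alpha <= 1:
        raise ValueError(f"alpha must exceed 1 for a normalizable tail, got {alpha}")
    if x_min <= 0:
        raise ValueError("x_min must be positive")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _as_rng(seed)
    r = rng.random(n)
    return x_min * (1.0 - r) ** (-1.0 / (alpha - 1.0))


@dataclass
class SimConfig:
    """Full parameterization of a synthetic arena walker.

    Defaults emulate the recorded study conditions: a 205 mm circular
    arena sampled at dt = 0.5 s for ~36,000 samples (5 h), a Levy
    exponent in the superdiffusive band, power-law waiting bouts, and a
    worker-scale walking speed of 10 mm/s.
    """

    model: str = "levy_walk"
    mu: float = 2.1  # move-duration (step) power-law exponent
    nu: float = 2.6  # waiting-time power-law exponent
    p_wait: float = 0.3  # probability of a waiting bout after each move
    speed: float = 10.0  # mm/s
    dt: float = 0.5  # s
    n_samples: int = 36000
    arena_diameter: float | None = 205.0  # mm
    boundary: str = "follow"
    x_min_step: float = 0.5  # s, minimum move duration
    x_min_wait: float = 0.5  # s, minimum waiting-bout duration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(
                f"boundary must be one of {BOUNDARIES}, got {self.boundary!r}"
            )
        if self.boundary != "none" and self.arena_diameter is None:
            raise ValueError("arena boundary requested without arena_diameter")
        if self.model == "levy_walk" and self.mu <= 1:
            raise ValueError("mu must exceed 1")
        if not 0.0 <= self.p_wait <= 1.0:
            raise ValueError("p_wait must lie in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.speed <= 0 or self.dt <= 0:
            raise ValueError("speed and dt must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# event-driven constant-speed walker


def _draw_segments(cfg: SimConfig, rng: np.random.Generator, total_time: float):
    """Draw (duration, heading, is_wait) move/wait segments covering total_time.

    A ballistic walker is a single move lasting the whole recording;
    a Levy walker alternates power-law move bouts (uniform random
    headings) with optional power-law waiting bouts.
    """
    if cfg.model == "ballistic":
        heading = rng.uniform(0.0, 2.0 * np.pi)
        return [(total_time, heading, False)]
    segments: list[tuple[float, float, bool]] = []
    t_acc = 0.0
    while t_acc < total_time:
        k = 4096
        taus = powerlaw_variates(cfg.mu, cfg.x_min_step, k, rng)
        headings = rng.uniform(0.0, 2.0 * np.pi, k)
        wait_coin = rng.random(k) < cfg.p_wait
        wait_taus = powerlaw_variates(cfg.nu, cfg.x_min_wait, k, rng)
        for tau, h, w, tw in zip(taus, headings, wait_coin, wait_taus):
            segments.append((float(tau), float(h), False))
            t_acc += tau
            if w:
                segments.append((float(tw), 0.0, True))
                t_acc += tw
            if t_acc >= total_time:
                break
    return segments


def _knots_unbounded(cfg: SimConfig, segments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dur = np.array([s[0] for s in segments])
    head = np.array([s[1] for s in segments])
    move = ~np.array([s[2] for s in segments])
    vx = np.where(move, cfg.speed * np.cos(head), 0.0)
    vy = np.where(move, cfg.speed * np.sin(head), 0.0)
    times = np.concatenate([[0.0], np.cumsum(dur)])
    xs = np.concatenate([[0.0], np.cumsum(vx * dur)])
    ys = np.concatenate([[0.0], np.cumsum(vy * dur)])
    return times, xs, ys


def _knots_bounded(cfg: SimConfig, segments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate segments inside the arena circle of radius R.

    'reflect': specular reflection off the wall, conserving the move's
    remaining duration.  'follow': on contact the walker continues
    along the wall (tangentially, keeping its angular sense) for the
    remaining move duration — a simple model of thigmotaxis.
    """
    R = cfg.arena_diameter / 2.0
    times = [0.0]
    xs = [0.0]
    ys = [0.0]
    p = np.zeros(2)
    t_now = 0.0
    max_arc_step = 0.1  # rad, chord-sampling resolution for wall arcs

    for dur, heading, is_wait in segments:
        if is_wait:
            t_now += dur
            times.append(t_now)
            xs.append(p[0])
            ys.append(p[1])
            continue
        u = np.array([np.cos(heading), np.sin(heading)])
        remaining = dur
        guard = 0
        while remaining > 0:
            guard += 1
            if guard > 100000:
                raise RuntimeError("boundary handling failed to terminate")
            b = float(p @ u)
            c = float(p @ p) - R * R
            disc = b * b - c
            d_hit = -b + np.sqrt(max(disc, 0.0))
            dist = cfg.speed * remaining
            at_wall = p @ p >= (R * (1 - 1e-12)) ** 2
            outward = b > 0
            if d_hit > 1e-12 and (d_hit >= dist or not (at_wall and outward)):
                if d_hit >= dist:
                    p = p + u * dist
                    t_now += remaining
                    remaining = 0.0
                    times.append(t_now)
                    xs.append(p[0])
                    ys.append(p[1])
                    continue
                p = p + u * d_hit
                t_hit = d_hit / cfg.speed
                t_now += t_hit
                remaining -= t_hit
                times.append(t_now)
                xs.append(p[0])
                ys.append(p[1])
            # now at the wall with time remaining
            nhat = p / np.linalg.norm(p)
            if cfg.boundary == "reflect":
                u = u - 2.0 * float(u @ nhat) * nhat
                p = nhat * R * (1 - 1e-12)
                continue
            # wall-following: slide along the circle for the rest of the move
            that = np.array([-nhat[1], nhat[0]])
            sense = 1.0 if float(u @ that) >= 0 else -1.0
            arc_angle = sense * cfg.speed * remaining / R
            n_sub = max(1, int(np.ceil(abs(arc_angle) / max_arc_step)))
            phi0 = np.arctan2(p[1], p[0])
            sub = phi0 + arc_angle * np.arange(1, n_sub + 1) / n_sub
            sub_t = t_now + remaining * np.arange(1, n_sub + 1) / n_sub
            r_in = R * (1 - 1e-12)
            times.extend(sub_t.tolist())
            xs.extend((r_in * np.cos(sub)).tolist())
            ys.extend((r_in * np.sin(sub)).tolist())
            p = np.array([r_in * np.cos(sub[-1]), r_in * np.sin(sub[-1])])
            t_now += remaining
            remaining = 0.0
    return np.asarray(times), np.asarray(xs), np.asarray(ys)


def _brownian(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian walker: per-axis increments N(0, (speed*dt/sqrt(2))**2).

    The per-sample rms displacement is speed*dt, so ``speed`` keeps the
    same meaning (typical distance covered per interval / dt) across
    models.
    """
    sigma = cfg.speed * cfg.dt / np.sqrt(2.0)
    inc = rng.normal(0.0, sigma, size=(cfg.n_samples - 1, 2))
    if cfg.boundary == "none":
        pos = np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
        return pos[:, 0], pos[:, 1]
    R = cfg.arena_diameter / 2.0
    pos = np.zeros((cfg.n_samples, 2))
    p = np.zeros(2)
    for i in range(1, cfg.n_samples):
        p = p + inc[i - 1]
        r = np.linalg.norm(p)
        if r > R:
            if cfg.boundary == "reflect":
                # radial fold: r -> 2R - r, same polar angle
                p = p * ((2.0 * R - r) / r)
                if np.linalg.norm(p) > R:  # pathological huge step
                    p = p * (R * (1 - 1e-12) / np.linalg.norm(p))
            else:  # follow: clamp onto the wall
                p = p * (R * (1 - 1e-12) / r)
        pos[i] = p
    return pos[:, 0], pos[:, 1]


def simulate_walker(cfg: SimConfig) -> Trajectory:
    """Simulate a walker and sample it on the regular dt grid.

    The continuous-time piecewise-linear path (move bouts at constant
    speed, waiting bouts at rest, boundary interactions) is sampled by
    linear interpolation at exact multiples of dt, mirroring a
    video-tracking readout.
    """
    rng = _as_rng(cfg.seed)
    grid_t = np.arange(cfg.n_samples, dtype=float) * cfg.dt
    if cfg.model == "brownian":
        x, y = _brownian(cfg, rng)
    else:
        segments = _draw_segments(cfg, rng, total_time=float(grid_t[-1]))
        if cfg.boundary == "none":
            times, xs, ys = _knots_unbounded(cfg, segments)
        else:
            times, xs, ys = _knots_bounded(cfg, segments)
        x = np.interp(grid_t, times, xs)
        y = np.interp(grid_t, times, ys)
    bounded = cfg.boundary != "none"
    return Trajectory(
        t=grid_t,
        x=x,
        y=y,
        arena_diameter=cfg.arena_diameter if bounded else None,
        arena_center=(0.0, 0.0) if bounded else None,
        id=f"sim-{cfg.model}-seed{cfg.seed}",
    )


# ---------------------------------------------------------------------------
# noise series


def relaxation_series(lam: float, n: int, seed=0) -> np.ndarray:
    """AR(1) relaxation return map x_{t+1} = lam*x_t + xi_t, x_0 = 0.

    ``xi_t`` are iid standard normal.  lam=0 gives white noise; as
    |lam| -> 1 the series becomes long-persistent with stationary
    variance 1/(1-lam**2).  Requires |lam| < 1.
    """
    if abs(lam) >= 1:
        raise ValueError(f"|lambda| must be < 1 for stationarity, got {lam}")
    if n < 2:
        raise ValueError("n must be at least 2")
    from scipy.signal import lfilter

    rng = _as_rng(seed)
    xi = rng.standard_normal(n)
    return lfilter([1.0], [1.0, -lam], xi)


def spectral_noise(beta: float, n: int, seed=0) -> np.ndarray:
    """Colored noise with expected power spectrum S(f) ~ 1/f**beta.

    White-noise Fourier coefficients are shaped by f**(-beta/2) and
    inverse-transformed; the output has zero mean and unit variance.
    beta=0 is white, beta=1 pink, beta=2 brown.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = _as_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spectrum = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x
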