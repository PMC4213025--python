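"""Single-individual trajectory handling.

Reads, validates, resamples and kinematically decomposes a tracked
individual's planar path into per-interval steps, turning angles,
waiting bouts and behavioural zone labels (wall-following, free
interior movement, static waiting) inside a circular arena.

Positions are in millimetres, time in seconds; the sampling interval
``dt`` is constant (video-tracking output at a fixed frame subsampling,
e.g. one point every 0.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "StepSeries",
    "WaitBout",
    "ZoneLabels",
    "read_trajectory",
    "resample",
    "compute_steps",
    "extract_waiting_bouts",
    "total_waiting_time",
    "label_zones",
    "turning_angle_histogram",
]

_DT_RTOL = 1e-9


@dataclass
class Trajectory:
    """Time-stamped planar positions of one individual.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with constant
        spacing ``dt`` (relative tolerance 1e-9).
    x, y : ndarray
        Positions in mm (already scaled from pixels if needed).
    arena_diameter : float or None
        Inner diameter of the circular arena in mm, when known.
    arena_center : (float, float) or None
        Arena center in track coordinates.  When None it is estimated
        as the bounding-box center of the track (adequate for a
        wall-following animal), and the containment check allows 1% of
        the radius as estimation slack.
    scale : float
        mm-per-pixel factor that was applied to the raw coordinates.
    id : str
        Free-text identifier.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_diameter: float | None = None
    arena_center: tuple[float, float] | None = None
    scale: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if not (n == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if n < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        diffs = np.diff(self.t)
        if np.any(diffs <= 0):
            raise ValueError("t must be strictly increasing")
        dt = float(np.median(diffs))
        if not np.allclose(diffs, dt, rtol=_DT_RTOL, atol=1e-12):
            k = int(np.argmax(np.abs(diffs - dt)))
            raise ValueError(
                f"non-constant sampling interval: spacing {diffs[k]:g} s at "
                f"index {k} differs from dt={dt:g} s"
            )
        if self.arena_diameter is not None:
            r = self.radius_from_center()
            rmax = float(r.max())
            limit = self.arena_diameter / 2.0
            slack = 1e-6 if self.arena_center is not None else 0.01 * limit
            if rmax > limit * (1 + 1e-9) + slack:
                raise ValueError(
                    f"positions extend {rmax:.3f} mm from the arena center "
                    f"but the arena radius is {limit:.3f} mm"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def center(self) -> tuple[float, float]:
        """Arena center: as stored, else the track's bounding-box center.

        For a wall-following animal the track's bounding circle is a
        good proxy for the arena itself; the true center is not stored
        in the deposited x,y tables.
        """
        if self.arena_center is not None:
            return (float(self.arena_center[0]), float(self.arena_center[1]))
        return (
            float((self.x.min() + self.x.max()) / 2.0),
            float((self.y.min() + self.y.max()) / 2.0),
        )

    def radius_from_center(self) -> np.ndarray:
        cx, cy = self.center()
        return np.hypot(self.x - cx, self.y - cy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class StepSeries:
    """Per-interval displacement lengths and signed turning angles.

    ``lengths[i]`` is the Euclidean distance covered between samples i
    and i+1 (length N-1 for N samples).  ``headings[i]`` is the atan2
    direction of that displacement, NaN for steps at or below
    ``zero_threshold``.  ``turns[i]`` is the wrapped heading change at
    the vertex between steps i and i+1 (length N-2), in [-pi, pi),
    NaN where either adjacent step is a zero-step.
    """

    dt: float
    lengths: np.ndarray
    headings: np.ndarray
    turns: np.ndarray
    source_id: str = ""
    zero_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        self.turns = np.asarray(self.turns, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("step lengths must be non-negative")
        finite = self.turns[np.isfinite(self.turns)]
        if finite.size and (finite.min() < -np.pi - 1e-12 or finite.max() > np.pi + 1e-12):
            raise ValueError("turning angles must lie in [-pi, pi)")

    @property
    def n_steps(self) -> int:
        return len(self.lengths)

    def zero_mask(self) -> np.ndarray:
        """Boolean mask of zero-steps (length <= zero_threshold)."""
        return self.lengths <= self.zero_threshold

    def to_frame(self) -> pd.DataFrame:
        turns = np.concatenate([[np.nan], self.turns])
        return pd.DataFrame(
            {"length": self.lengths, "heading": self.headings, "turn": turns}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class WaitBout:
    """A maximal run of consecutive zero-displacement intervals."""

    start_index: int
    n_samples: int
    duration: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("a bout spans at least one sampling interval")
        if self.duration <= 0:
            raise ValueError("bout duration must be positive")


@dataclass
class ZoneLabels:
    """Per-sample behavioural zone: 'wall', 'interior' or 'waiting'."""

    labels: np.ndarray
    wall_band: float

    def __post_init__(self) -> None:
        allowed = {"wall", "interior", "waiting"}
        bad = set(np.unique(self.labels)) - allowed
        if bad:
            raise ValueError(f"unknown zone labels: {sorted(bad)}")

    def occupancy(self) -> dict[str, float]:
        n = len(self.labels)
        return {
            z: float(np.count_nonzero(self.labels == z)) / n
            for z in ("wall", "interior", "waiting")
        }

    def to_csv(self, path) -> None:
        pd.DataFrame({"zone": self.labels}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reading


def read_trajectory(
    path,
    dt: float | None = None,
    scale: float = 1.0,
    arena_diameter: float | None = None,
    id: str | None = None,
) -> Trajectory:
    """Read a delimited text table of (x, y) or (t, x, y) columns.

    The delimiter is auto-detected among comma/tab/whitespace and a
    single non-numeric header line is skipped.  With two columns the
    sample clock is synthesized as 0, dt, 2*dt, ... (``dt`` required);
    with three columns the first is taken as time and, when ``dt`` is
    also given, checked against it.  Positions are multiplied by
    ``scale`` (mm per pixel).
    """
    raw = pd.read_csv(
        path, sep=None, engine="python", header=None, comment="#", dtype=str
    )
    raw = raw.dropna(how="all")
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")

    def _row_numeric(row) -> bool:
        try:
            [float(v) for v in row]
            return True
        except (TypeError, ValueError):
            return False

    header_skipped = 0
    if not _row_numeric(raw.iloc[0]):
        raw = raw.iloc[1:]
        header_skipped = 1
        if raw.shape[0] == 0:
            raise ValueError(f"{path}: only a header line, no data rows")

    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1).to_numpy()
    if bad.any():
        row = int(np.argmax(bad)) + 1 + header_skipped
        raise ValueError(f"{path}: non-numeric or missing value at data row {row}")

    ncol = num.shape[1]
    if ncol == 2:
        if dt is None:
            raise ValueError("dt is required for 2-column (x, y) input")
        x = num.iloc[:, 0].to_numpy(float)
        y = num.iloc[:, 1].to_numpy(float)
        t = np.arange(len(x), dtype=float) * dt
    elif ncol == 3:
        t = num.iloc[:, 0].to_numpy(float)
        x = num.iloc[:, 1].to_numpy(float)
        y = num.iloc[:, 2].to_numpy(float)
        if dt is not None and len(t) > 1:
            inferred = float(np.median(np.diff(t)))
            if not np.isclose(inferred, dt, rtol=1e-6):
                raise ValueError(
                    f"file time spacing {inferred:g} s contradicts dt={dt:g} s"
                )
    else:
        raise ValueError(f"{path}: expected 2 or 3 columns, found {ncol}")

    if len(x) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    return Trajectory(
        t=t,
        x=x * scale,
        y=y * scale,
        arena_diameter=arena_diameter,
        scale=scale,
        id=id if id is not None else str(path),
    )


# ---------------------------------------------------------------------------
# kinematics


def resample(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th sample (coarser sampling rate).

    The retained positions are unchanged, so each coarse displacement is
    exactly the vector sum of the intervening fine steps; ``dt`` is
    multiplied by ``factor``.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return replace(traj)
    if (traj.n_samples - 1) // factor < 1:
        raise ValueError("resampling would leave fewer than 2 samples")
    return Trajectory(
        t=traj.t[::factor],
        x=traj.x[::factor],
        y=traj.y[::factor],
        arena_diameter=traj.arena_diameter,
        arena_center=traj.arena_center,
        scale=traj.scale,
        id=traj.id,
    )


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi); an exact reversal maps to -pi."""
    return np.mod(theta + np.pi, 2.0 * np.pi) - np.pi


def compute_steps(traj: Trajectory, zero_threshold: float = 0.0) -> StepSeries:
    """Decompose a trajectory into step lengths, headings and turns.

    ``zero_threshold`` (mm) flags steps with length at or below it as
    zero-steps: their heading is undefined (NaN) and turning angles are
    undefined across them.  The default 0 treats only exactly-zero
    displacements as stationary.
    """
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    lengths = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    headings[lengths <= zero_threshold] = np.nan
    turns = _wrap_angle(headings[1:] - headings[:-1])
    turns[~np.isfinite(headings[1:]) | ~np.isfinite(headings[:-1])] = np.nan
    return StepSeries(
        dt=traj.dt,
        lengths=lengths,
        headings=headings,
        turns=turns,
        source_id=traj.id,
        zero_threshold=zero_threshold,
    )


def extract_waiting_bouts(
    steps: StepSeries, zero_threshold: float | None = None
) -> list[WaitBout]:
    """Maximal runs of consecutive zero-steps as waiting bouts.

    A bout of k consecutive zero-displacement intervals lasts k*dt
    seconds, so the minimum reportable duration is one sampling
    interval.  Returns an empty list when the animal never pauses.
    """
    thr = steps.zero_threshold if zero_threshold is None else zero_threshold
    mask = steps.lengths <= thr
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        WaitBout(start_index=int(s), n_samples=int(e - s), duration=float((e - s) * steps.dt))
        for s, e in zip(starts, ends)
    ]


def total_waiting_time(waits: list[WaitBout]) -> float:
    """Sum of bout durations in seconds."""
    return float(sum(w.duration for w in waits))


def label_zones(
    traj: Trajectory, wall_band: float = 10.0, waits: list[WaitBout] | None = None
) -> ZoneLabels:
    """Label every sample as wall-following, interior or waiting.

    A sample is 'wall' when its distance to the arena boundary is at
    most ``wall_band`` mm (default two body lengths, ~10 mm), 'waiting'
    when covered by a waiting bout (waiting takes precedence over
    wall), else 'interior'.  Zone labels are descriptive output only;
    no estimator in the package consumes them.
    """
    if traj.arena_diameter is None:
        raise ValueError("label_zones requires arena_diameter")
    r = traj.radius_from_center()
    boundary_dist = traj.arena_diameter / 2.0 - r
    labels = np.full(traj.n_samples, "interior", dtype=object)
    labels[boundary_dist <= wall_band] = "wall"
    if waits:
        for w in waits:
            # a run of k zero-steps starting at step s pins samples s..s+k
            labels[w.start_index : w.start_index + w.n_samples + 1] = "waiting"
    return ZoneLabels(labels=labels, wall_band=float(wall_band))


def turning_angle_histogram(
    steps: StepSeries, n_bins: int = 36
) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram of turning angles over [-180, 180) degrees.

    Returns ``(bin_centers_deg, probabilities)`` with the probabilities
    summing to 1.  Raises if the series has no defined turns (all steps
    zero or only two samples).
    """
    turns = steps.turns[np.isfinite(steps.turns)]
    if turns.size == 0:
        raise ValueError("no defined turning angles in this series")
    counts, edges = np.histogram(np.degrees(turns), bins=n_bins, range=(-180.0, 180.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / counts.sum()
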