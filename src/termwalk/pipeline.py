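"""Full per-trajectory analysis and machine-readable report.

``analyze`` runs every stage of the pipeline — step decomposition, MSD
and anomalous-diffusion exponent, structure functions, power spectrum,
autocorrelation, IFS occupancy, waiting-time tail fit, turning angles,
zone occupancy and the sampling-rate dependence table — and collects
the results into one JSON-serializable report.  A failing stage is
recorded as ``{"error": ...}`` without stopping the others, so a short
or degenerate track still yields a partial report.

The report lists the two independent Levy-exponent routes side by
side: mu_alpha = 4 - alpha from the MSD and mu_q = 1 + 1/H from the
zeta(q) slope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np

from . import __version__
from . import diffusion, fluctuation, heavytail, structure
from .trajectory import (
    Trajectory,
    compute_steps,
    extract_waiting_bouts,
    label_zones,
    resample,
    total_waiting_time,
    turning_angle_histogram,
)

__all__ = [
    "AnalysisConfig",
    "analyze",
    "sampling_rate_table",
    "report_to_json",
    "load_report_schema",
    "validate_report",
]


@dataclass
class AnalysisConfig:
    """Tunable knobs of the per-trajectory pipeline."""

    zero_threshold: float = 0.0  # mm; steps at/below are stationary
    wall_band: float = 10.0  # mm; wall-zone width (~2 body lengths)
    msd_points_per_decade: int = 25
    msd_window: tuple[float, float] | None = None  # s; None = 2dt..5% duration
    q_orders: tuple[int, ...] = tuple(range(1, 9))
    structure_max_lag: int = 1000  # samples (also capped at n/10)
    structure_fit_window: tuple[float, float] | None = None  # lags, samples
    psd_segment_length: int = 4096
    acf_max_lag: int = 1000  # samples (also capped below n/2)
    waiting_x_min: float | str = "scan"
    turning_bins: int = 36
    sampling_factors: tuple[int, ...] = (1, 4, 10)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["msd_window"] = list(d["msd_window"]) if d["msd_window"] else None
        d["structure_fit_window"] = (
            list(d["structure_fit_window"]) if d["structure_fit_window"] else None
        )
        d["q_orders"] = list(d["q_orders"])
        d["sampling_factors"] = list(d["sampling_factors"])
        return d


def _stage(report: dict, name: str, fn) -> None:
    try:
        report["stages"][name] = fn()
    except Exception as exc:  # stage isolation is the contract
        report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}


def analyze(traj: Trajectory, config: AnalysisConfig | None = None) -> dict:
    """Run the full analysis pipeline on one trajectory.

    Returns a plain-dict report (see ``report_schema.json``); use
    :func:`report_to_json` for a canonical byte-stable serialization.
    """
    cfg = config or AnalysisConfig()
    report: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "trajectory": {
            "id": traj.id,
            "n_samples": int(traj.n_samples),
            "dt_s": float(traj.dt),
            "duration_s": float(traj.duration),
            "arena_diameter_mm": (
                float(traj.arena_diameter) if traj.arena_diameter is not None else None
            ),
        },
        "stages": {},
    }

    steps = compute_steps(traj, zero_threshold=cfg.zero_threshold)
    waits = extract_waiting_bouts(steps)

    def stage_steps():
        zero = int(np.count_nonzero(steps.zero_mask()))
        moving = steps.lengths[~steps.zero_mask()]
        return {
            "n_steps": int(steps.n_steps),
            "n_zero_steps": zero,
            "mean_step_mm": float(moving.mean()) if moving.size else 0.0,
            "max_step_mm": float(steps.lengths.max()),
        }

    def stage_msd():
        delays = diffusion.default_delays(traj, cfg.msd_points_per_decade)
        curve = diffusion.msd(traj, delays)
        fit = diffusion.fit_anomalous_exponent(curve, window=cfg.msd_window)
        alpha = fit.exponent
        return {
            "alpha": alpha,
            "alpha_stderr": fit.stderr,
            "diffusion_coefficient": fit.prefactor,
            "r_squared": fit.r_squared,
            "fit_window_s": list(fit.fit_window),
            "mu_alpha": diffusion.mu_from_alpha(alpha) if 1 <= alpha <= 2 else 4.0 - alpha,
            "classification": diffusion.classify_diffusion(alpha),
        }

    def stage_structure():
        max_lag = min(cfg.structure_max_lag, traj.n_samples // 10)
        lags = structure.default_lags(traj.n_samples, max_fraction=max_lag / traj.n_samples)
        sfs = structure.trajectory_structure_functions(traj, q=cfg.q_orders, lags=lags)
        sfs = structure.fit_zeta(sfs, window=cfg.structure_fit_window)
        H, mu_q = structure.H_and_mu(sfs)
        return {
            "q": [float(v) for v in sfs.q],
            "zeta": [float(v) for v in sfs.zeta_values()],
            "zeta_stderr": [float(f.stderr) for f in sfs.zeta],
            "H": H,
            "H_stderr": sfs.H_stderr,
            "mu_q": mu_q,
            "classification": structure.classify_H(H),
        }

    def stage_spectrum():
        spec = fluctuation.power_spectrum(steps, segment_length=cfg.psd_segment_length)
        return {
            "beta": spec.beta.exponent,
            "beta_stderr": spec.beta.stderr,
            "r_squared": spec.beta.r_squared,
            "segment_length": spec.segment_length,
            "n_segments": spec.n_segments,
        }

    def stage_acf():
        max_lag = min(cfg.acf_max_lag, steps.n_steps // 2 - 1)
        acf = fluctuation.autocorrelation(steps, max_lag=max_lag)
        fit = fluctuation.fit_acf_decay(acf)
        return {
            "gamma": fit.exponent,
            "gamma_stderr": fit.stderr,
            "r_squared": fit.r_squared,
            "max_lag": int(max_lag),
            "classification": fluctuation.classify_acf_decay(fit),
        }

    def stage_ifs():
        cloud = fluctuation.ifs_map(steps)
        return {
            "n_points": int(cloud.n_points),
            "occupancy_16": fluctuation.ifs_occupancy(cloud, grid=16),
        }

    def stage_waiting():
        fit = heavytail.fit_waiting_times(waits, x_min=cfg.waiting_x_min)
        durations = [w.duration for w in waits]
        return {
            "exponent": fit.exponent,
            "stderr": fit.stderr,
            "x_min_s": fit.x_min,
            "n_tail": fit.n_tail,
            "ks_distance": fit.ks_distance,
            "method": fit.method,
            "n_bouts": len(waits),
            "total_waiting_s": total_waiting_time(waits),
            "max_bout_s": max(durations),
        }

    def stage_turning():
        centers, probs = turning_angle_histogram(steps, n_bins=cfg.turning_bins)
        turns = steps.turns[np.isfinite(steps.turns)]
        Rbar = float(np.abs(np.mean(np.exp(1j * turns))))
        mean_deg = float(np.degrees(np.angle(np.mean(np.exp(1j * turns)))))
        circ_sd = float(np.degrees(np.sqrt(max(-2.0 * np.log(Rbar), 0.0)))) if Rbar > 0 else float("inf")
        return {
            "n_turns": int(turns.size),
            "bin_centers_deg": [float(c) for c in centers],
            "probability": [float(p) for p in probs],
            "mean_deg": mean_deg,
            "circular_std_deg": circ_sd,
        }

    def stage_zones():
        zones = label_zones(traj, wall_band=cfg.wall_band, waits=waits)
        occ = zones.occupancy()
        occ["wall_band_mm"] = cfg.wall_band
        return occ

    def stage_sampling():
        return sampling_rate_table(
            traj, factors=cfg.sampling_factors, zero_threshold=cfg.zero_threshold
        )

    _stage(report, "steps", stage_steps)
    _stage(report, "msd", stage_msd)
    _stage(report, "structure", stage_structure)
    _stage(report, "spectrum", stage_spectrum)
    _stage(report, "acf", stage_acf)
    _stage(report, "ifs", stage_ifs)
    _stage(report, "waiting", stage_waiting)
    _stage(report, "turning", stage_turning)
    _stage(report, "zones", stage_zones)
    _stage(report, "sampling_rate", stage_sampling)
    return report


def sampling_rate_table(
    traj: Trajectory,
    factors=(1, 4, 10),
    zero_threshold: float = 0.0,
    bins_per_decade: int = 10,
) -> list[dict]:
    """Step-length statistics under coarser and coarser sampling.

    For each resampling factor the trajectory is thinned, decomposed
    into steps, and the non-zero step lengths are log-binned and (when
    at least 10 remain) tail-fitted by scanned-x_min MLE.  The table
    exposes how strongly an apparent step-length exponent depends on
    the sampling rate — the central caveat against histogram-only
    power-law claims.
    """
    rows = []
    for f in factors:
        sub = resample(traj, f)
        steps = compute_steps(sub, zero_threshold=zero_threshold)
        lengths = steps.lengths[steps.lengths > zero_threshold]
        row: dict = {
            "factor": int(f),
            "dt_s": float(sub.dt),
            "n_steps": int(steps.n_steps),
            "n_nonzero": int(lengths.size),
            "mean_step_mm": float(lengths.mean()) if lengths.size else 0.0,
        }
        if lengths.size >= 10:
            try:
                log_binned = heavytail.log_binned_histogram(
                    lengths, bins_per_decade=bins_per_decade
                )
                row["n_bins"] = int(len(log_binned.centers))
            except ValueError:
                pass
            try:
                fit = heavytail.mle_powerlaw(lengths, x_min="scan")
                row.update(
                    exponent=fit.exponent,
                    stderr=fit.stderr,
                    x_min_mm=fit.x_min,
                    n_tail=fit.n_tail,
                    ks_distance=fit.ks_distance,
                )
            except ValueError as exc:
                row["fit_error"] = str(exc)
        else:
            row["fit_error"] = "fewer than 10 non-zero steps"
        rows.append(row)
    return rows


def report_to_json(report: dict, path=None) -> str:
    """Canonical (sorted-keys) JSON; byte-identical for identical runs."""
    text = json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_report_schema() -> dict:
    """The published report schema shipped with the package."""
    with resources.files("termwalk").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Structural validation of a report against the shipped schema.

    Checks the required top-level keys and per-stage shapes declared in
    ``report_schema.json``; raises ``ValueError`` on the first
    violation.  (Intentionally a light structural checker, not a full
    JSON-Schema engine.)
    """
    schema = load_report_schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if not isinstance(report["stages"], dict):
        raise ValueError("'stages' must be an object")
    stage_schemas = schema["properties"]["stages"]["properties"]
    for name, stage in report["stages"].items():
        if name == "sampling_rate":
            if not isinstance(stage, (list, dict)):
                raise ValueError("'sampling_rate' must be a list (or error object)")
            continue
        if not isinstance(stage, dict):
            raise ValueError(f"stage {name!r} must be an object")
        if "error" in stage:
            if not isinstance(stage["error"], str):
                raise ValueError(f"stage {name!r} error must be a string")
            continue
        required = stage_schemas.get(name, {}).get("required", [])
        for key in required:
            if key not in stage:
                raise ValueError(f"stage {name!r} missing required field {key!r}")
    msd_stage = report["stages"].get("msd", {})
    if "alpha" in msd_stage and "mu_alpha" in msd_stage:
        if abs(msd_stage["mu_alpha"] - (4.0 - msd_stage["alpha"])) > 1e-12:
            raise ValueError("report violates mu_alpha = 4 - alpha")
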