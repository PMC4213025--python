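# termwalk

Scaling analysis of single-animal arena trajectories — built for the
exploratory behaviour of isolated termite workers walking in a circular
dish, and applicable to any fixed-interval (x, y, t) track of one
individual.

Movement-ecology studies often test for Lévy-like movement by fitting a
power law to a step-length histogram and stopping there. That single
number is fragile: it depends strongly on the sampling rate, and it
ignores the rest of the dynamics. `termwalk` instead characterizes a
track through several mutually constraining routes:

* **Anomalous diffusion.** The time-averaged mean-squared displacement
  `MSD(Δ) = ⟨|r(t+Δ) − r(t)|²⟩ ∝ Δ^α`; α = 1 is normal diffusion, α = 2
  ballistic. For a superdiffusive Lévy walk the step exponent follows as
  **μ = 4 − α**.
* **Kolmogorov structure functions.** `S_q(τ) = ⟨|r(t+τ) − r(t)|^q⟩ ∝
  τ^ζ(q)`; the slope H of ζ(q) versus q gives an independent estimate
  **μ = 1 + 1/H** (H = 1/2 is normal diffusion, 1/2 < H ≤ 1
  superdiffusive).
* **Temporal fluctuations.** FFT power spectrum of the step-length
  series (`S(f) ∝ 1/f^β`: white β=0, pink β=1, brown β=2), the
  autocorrelation function `C(τ)` with power-law long-memory decay
  `C ∝ τ^−γ`, and a chaos-game (IFS) map that renders temporal
  self-similarity as fractal spatial structure.
* **Heavy tails by MLE.** Waiting-bout durations (maximal runs of
  zero displacement) and step lengths fitted with the continuous
  maximum-likelihood estimator `α̂ = 1 + n/Σ ln(x_i/x_min)`, with the
  cutoff chosen by Kolmogorov–Smirnov scan.
* **Kinematics.** Step decomposition, turning-angle distributions,
  wall/interior/waiting zone occupancy, and a sampling-rate table that
  quantifies how apparent step-length exponents move with the sampling
  interval.

A synthetic module (constant-speed Lévy walkers with power-law waiting
bouts and circular-arena confinement, Brownian and ballistic controls,
power-law variates, AR(1) relaxation maps, 1/f^β noise) makes every
estimator verifiable by parameter recovery, with no data download.

## Worked example

Simulate five hours of a confined Lévy walker (μ = 2.1, waiting
exponent ν = 2.6, 205 mm arena with wall-following, one sample every
0.5 s) and run the full pipeline. Confinement saturates the MSD once
the walker has crossed the dish (~20 s), so the scaling fits use
pre-saturation windows, just as one would for a real confined animal:

```python
import termwalk as tw

cfg = tw.SimConfig(model="levy_walk", mu=2.1, nu=2.6, p_wait=0.3,
                   speed=10.0, dt=0.5, n_samples=36000,
                   arena_diameter=205.0, boundary="follow", seed=42)
traj = tw.simulate_walker(cfg)

acfg = tw.AnalysisConfig(msd_window=(1.0, 15.0), structure_fit_window=(2, 30))
report = tw.analyze(traj, acfg)
```

Formatting the relevant `report["stages"]` fields gives:

```
alpha (MSD slope)      : 1.777  -> mu_alpha = 2.223 (superdiffusive)
H (zeta(q) slope)      : 0.960  -> mu_q     = 2.042
spectral exponent beta : 0.78
waiting-time exponent  : 2.39  (x_min = 4.0 s, 805 bouts, longest 235.5 s)
zone occupancy         : wall 0.61 / interior 0.29 / waiting 0.10
IFS 16x16 occupancy    : 0.74
```

Read it as: the walker is clearly superdiffusive (α ≈ 1.78), and the
two independent Lévy-exponent routes bracket the generator's μ = 2.1;
the step series sits between pink and brown noise; waiting bouts are
power-law over three decades of duration; the walker spends most of its
time within two body lengths of the wall — all features observed in
real termite tracks. The IFS occupancy well below 1 flags temporal
structure an iid series would not have.

The same pipeline runs from the shell:

```sh
termwalk simulate --model levy --mu 2.1 --n 36000 --dt 0.5 \
    --arena 205 --seed 42 --out traj.csv
termwalk analyze --input traj.csv --arena 205 --out report.json
termwalk selftest
```

`analyze` accepts 2-column (x, y) or 3-column (t, x, y) delimited text
(`--dt` and `--scale` supply the clock and mm-per-pixel factor for raw
tracker output) and writes a versioned JSON report listing both
exponent routes side by side; `report_schema.json` ships with the
package.

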