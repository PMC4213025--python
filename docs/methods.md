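# Methods

This note records the models, estimators, numerical choices and known
limitations of `termwalk`, in the order the pipeline runs them.

## Trajectories and steps

A trajectory is a constant-interval sample of one individual's planar
position: times `t` (s), positions `x, y` (mm), optional arena diameter
and center. The sampling interval `dt` must be constant to a relative
tolerance of 1e-9; the reference recordings use dt = 0.5 s over 35,000
to 43,000 samples (about 5 h). When the arena center is unknown it is
estimated as the bounding-box center of the track — adequate for
wall-following animals that trace out the arena rim — and the
containment check then allows 1% of the radius as estimation slack.

Steps are the per-interval displacements; the step length series
`l(t)` drives the spectral, autocorrelation and IFS analyses. Turning
angles are wrapped heading differences in [−π, π), with an exact
reversal mapped to −π; they are undefined (NaN) whenever either
adjacent step is a zero-step. These conventions are internal choices —
nothing downstream depends on the sign given to a perfect reversal.

Zero-steps default to *exactly* zero displacement (`zero_threshold =
0 mm`). Real trackers emit sub-pixel jitter; the threshold is
configurable for such data, but the default reflects a tracker that
reports unchanged positions as unchanged. Waiting bouts are maximal
runs of consecutive zero-steps; a run of k zero-steps lasts exactly
k·dt, so total waiting time equals dt times the number of zero-steps,
an identity the tests assert exactly.

Zone labels (wall / interior / waiting) are descriptive output only.
The wall band defaults to 10 mm ≈ two body lengths; waiting takes
precedence over wall. No estimator consumes zone labels.

`resample(traj, k)` keeps every k-th sample, so coarse displacements
are exactly vector sums of the fine ones. The sampling-rate table
(factors 1, 4, 10 by default, i.e. 0.5 s, 2 s, 5 s) exists to expose
how strongly an apparent step-length exponent depends on this choice.

## Synthetic walkers

The Lévy walker is a *walk*, not a flight: it moves at constant speed
along a uniformly random heading for a power-law duration τ ~ τ^−μ
(τ ≥ x_min_step), optionally pauses (probability `p_wait`) for a
power-law waiting duration ~ τ^−ν, and is then sampled on the regular
dt grid by linear interpolation — mirroring a video-tracking readout.
The walk construction (rather than instantaneous jumps) is what makes
the MSD exponent finite and tied to μ by α = 4 − μ in 2 < μ < 3.

Defaults are the recorded study conditions: dt = 0.5 s, 36,000
samples, 205 mm arena, μ = 2.1, ν = 2.6, x_min = one sampling
interval. Walking speed defaults to 10 mm/s and `p_wait` to 0.3 —
worker-scale values chosen once as realistic for a ~5 mm insect that
alternates runs with frequent brief pauses; neither is critical to any
estimator test, which all use explicit configurations.

Boundary handling: `reflect` is specular reflection off the arena
circle (closed-form chord intersection, iterated within a move);
`follow` models thigmotaxis — on contact the walker slides along the
wall tangentially, keeping its angular sense, for the remainder of the
move (arcs are emitted as chords subtending ≤ 0.1 rad, a ≤ 0.13 mm
chord error at R = 102.5 mm). The Brownian control uses per-axis
Gaussian increments with rms per-sample displacement `speed·dt`, and
radial folding at the wall.

Noise generators: `powerlaw_variates` is the inverse-transform
x = x_min(1−r)^(−1/(α−1)); `relaxation_series` is the AR(1) map
x_{t+1} = λx_t + ξ_t with standard-normal ξ (λ = 0 white noise,
variance → 1/(1−λ²)); `spectral_noise` shapes white-noise Fourier
coefficients by f^(−β/2). All generators are bit-reproducible under a
fixed seed.

## MSD and the diffusion route to μ

The MSD is time-averaged with overlapping origins (all (t, t+Δ)
pairs); overlapping was chosen over disjoint pairs for variance
reduction. Delays are log-spaced multiples of dt, 25 per decade,
up to 5% of the track duration by default: confined tracks saturate at
large Δ (the walker has crossed the arena), and the default window
2·dt – 5%·T for the log-log slope fit avoids both single-interval
discreteness and that saturation. For strongly confined tracks even 5%
is too long — the worked example fits 1–15 s in a 205 mm arena — so
the window is always user-overridable and is reported in the fit.

α classifies the motion (subdiffusive / normal / superdiffusive;
α = 2 is the ballistic bound for a finite-speed walker) and converts
to a Lévy exponent by μ = 4 − α, valid for 1 ≤ α ≤ 2. Outside that
band the conversion still returns a value but warns: it is an
extrapolation beyond the Lévy-walk regime.

At μ = 2 exactly, the Lévy-walk MSD carries a logarithmic correction
(∼ t²/ln t); the measured slope over lags 2–1000 samples is ≈ 1.90,
not 2.0. The recovery tests assert ±0.1 around 4 − μ for μ ∈
{2.2, 2.5} and the band [1.80, 2.0] at μ = 2.0 for this reason.

## Structure functions and the ζ(q) route to μ

`S_q(τ) = ⟨|r(t+τ) − r(t)|^q⟩` over all overlapping origins — the
traveled distance coarse-grained at lag τ, so ζ(2) is the MSD exponent
by construction. A scalar-series variant (increments
`|x(t+τ) − x(t)|`) is provided for arbitrary series. Lags are
log-spaced integers, 20 per decade, from 1 sample to a tenth of the
series (the lag-grid construction is an implementation choice). ζ(q)
is fitted per q on log-log axes; lags with S_q = 0 are dropped. H is
the least-squares slope of ζ(q) versus q for q = 1..8, with a free
intercept (reported via its standard error); μ_q = 1 + 1/H.

**Known limitation — when the two routes disagree.** For an
*untruncated* Lévy walk the moments are bifractal: ζ(q) = q/(μ−1) only
below q = μ−1 (< 2 in the superdiffusive band), while all higher
orders are carried by the longest ballistic flights, ζ(q) = q + 3 − μ.
A line fitted through q = 1..8 then has slope H ≈ 1, so μ_q saturates
near 2 regardless of μ, and the gap between the two routes grows like
μ − 2. Near μ = 2.1 both routes agree within ~0.13; at μ = 2.3 the
ζ(q) route reads ≈ 2.0 while 4 − α̂ correctly reads ≈ 2.3. On real
confined tracks the arena truncates the longest flights and the
observed ζ(q) is much closer to a single line — which is why the two
routes can agree well on measured animals while disagreeing on ideal
unbounded walks. The tests encode exactly this behaviour rather than
an idealized closure.

## Spectrum, autocorrelation, IFS

The power spectrum is a plain FFT periodogram of mean-removed
consecutive segments (4096 samples by default, matching the analysis
scale of the reference recordings), averaged across all full segments,
normalized so the one-sided power sums to the series variance
(Parseval, asserted to 1e-6). A Hann taper is available but off by
default — fidelity to the plain-FFT convention. β is the negated
log-log slope over [4/L, Nyquist/4], away from the DC edge and the
aliasing corner.

The ACF uses the (N−τ)-normalized estimator
`C(τ) = Σ(l_t−⟨l⟩)(l_{t+τ}−⟨l⟩) / ((N−τ)σ²)` with the full-series
variance, so C(0) = 1 exactly; the biased 1/N variant was rejected for
fidelity to the stated form. γ is the negated log-log slope of the
positive part of C; 0 < γ < 1 with r² ≥ 0.95 is classified as long
memory, a poor r² (e.g. exponential decay) is flagged rather than
reported as a power law. Note the estimator's own sampling noise at
lag τ is ≈ √((1+λ²)/(1−λ²))/√N for AR(1)-like series, so closed-form
comparisons are meaningful only at lags where the signal exceeds that
floor.

The IFS (chaos game) map bins the series by its quartiles — a
parameter-free choice consistent with the chaos-game literature —
assigns the four bins to the corners (0,0), (1,0), (0,1), (1,1) in
that fixed order, and iterates p_{n+1} = (p_n + corner)/2 from
(0.5, 0.5). Correlated series leave fractal voids; iid series fill the
square (occupancy of a 16×16 grid ≥ 95% at n = 10⁵, and permuting a
correlated series pushes occupancy toward the iid value). Constant
series have degenerate quartiles and are rejected.

## Heavy-tail MLE

Continuous MLE `α̂ = 1 + n/Σ ln(x_i/x_min)` with KS goodness; with
`x_min="scan"` the cutoff minimizes the KS distance over candidate
data values (thinned to ≤ 100 log-evenly spaced candidates for speed).
Two guards keep the scan meaningful on data that are *not* power laws:
the selected tail must contain at least max(10, √n) points, and must
span at least a factor 2 in value. Without them the scan latches onto
point-mass atoms — e.g. the step-length cap v·dt of a constant-speed
walker, where an all-equal tail is "fitted" perfectly by α → ∞. Pure
power-law recovery is unaffected (x_min within one log-bin, α within
±0.05 at n = 10⁵).

Waiting-bout durations are discrete multiples of dt fitted with the
continuous estimator; the admissible cutoff is floored at dt, and
scanning (the default) in practice selects cutoffs of several dt,
where discreteness bias is small. Fixing x_min at 2·dt on strongly
discretized durations biases α̂ upward by ~0.1–0.2; x_min ≥ 2·dt plus
scanning is the recommended combination, and a discrete MLE is a noted
extension. The reported standard error is the asymptotic
(α̂−1)/√n_tail, or a seeded 200-resample bootstrap on request. No
likelihood-ratio model comparison is performed — only the exponent and
KS distance are reported.

Log-binned histograms (geometric bins, default 10 per decade,
zero-count bins retained, density normalized to unit integral) are
descriptive companions to the MLE, never the estimator.

## Pipeline and report

`analyze` runs all stages independently; a stage failure is recorded
as an error string and the rest still run (a track without arena
metadata simply has no zone stage, a track without pauses no waiting
fit). Reports are plain dicts, serialized with sorted keys so
identical configurations produce byte-identical files; the structural
schema ships as `report_schema.json` and `validate_report` checks
required keys, per-stage fields and the exact identity
μ_alpha = 4 − α (to 1e-12). Plots are optional helpers and never
required by tests.

## Problem sizes used in tests

Stochastic recovery tests run at the sizes where their tolerances are
comfortably met by the estimators' sampling theory: 10⁶ grid samples
for Lévy-walk exponent recovery and waiting-time round trips, 10⁵ for
Brownian controls, MLE recovery and generator-law checks (KS,
ACF, spectral slopes), 100 seeded replicates at 10⁴ for the estimator
bias check. Exact oracle-equivalence checks (brute-force double loops
for MSD, structure functions, ACF) run on ≤ 500-sample inputs. The
full suite completes in well under a minute of compute beyond the two
session-scoped 10⁶-sample simulations.

## What the synthetic generators do not emulate

Tracker pixel quantization and sub-pixel jitter (real zero-steps are
threshold judgements), body-length-scale wobble, heterogeneous
behaviour over hours (fatigue, thigmotactic habituation), and any
social or chemical context. Passing recovery tests therefore shows the
estimators are correct on their assumed generative models — not that a
given real track is a Lévy walk. The package's design position is
precisely that such a claim needs the convergence of several
independent probes, not one histogram fit.
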