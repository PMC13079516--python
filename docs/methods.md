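# Methods

## Model

The package treats subjective time as a gain transformation of objective
time: an objective interval Δt is experienced as κ(t)·Δt, and a periodic
internal clock of objective period τ_p runs at subjective period κ(t)·τ_p.
The relative deviation D_r = κ − 1 measures the mismatch; precision is
defined as P = 1/|D_r| and diverges at veridical timing (κ = 1).  We
return an explicit `inf` sentinel there and provide a regularized variant
P_ε = 1/max(|D_r|, ε) (default ε = 1e−6) for plotting and fitting.

Restoration of veridical timing is modeled as a linear second-order
system, D̈_r = −a·D_r − b·Ḋ_r with a (1/s²) the restoring stiffness and
b (1/s) viscous damping.  The damping requirement reflects the modeling
assumption that the clock should not ring around κ = 1: parameters with
b² < 4a are accepted but flagged with a warning.  The same equation
governs the absolute deviation D_a = τ_p·D_r when τ_p is constant, so D_a
is exposed only through that identity rather than solved separately.
Units: t is in seconds; only the ratios of (a, b) matter under time
rescaling, which is documented rather than normalized away.

κ must stay positive for a subjective-time rate to be meaningful, i.e.
D_r > −1.  Initial states violating this are rejected; trajectories that
cross the bound trigger a warning rather than being clipped, because
clipping would silently change the dynamics.

## Solvers

The homogeneous equation is solved in closed form on all three branches
(two real exponentials / critically damped / damped cosine), selecting
the critical branch when |b² − 4a| ≤ 1e−12·max(b², 4a).  The numerical
path is a fixed-step classical RK4 whose step is
min(0.01, 0.03/max(√a, b)) s — tied to the fastest system timescale so the
global truncation error stays below ~1e−9 over a 10 s horizon, and fixed
(rather than adaptive) so runs are bit-reproducible.  Integration nodes
always include the sample grid and any forcing breakpoints, so RK4 never
steps across a discontinuity of the challenge input.  Tests cross-check
the integrator against both the analytic solution and an independent
high-order adaptive integrator.

External challenges (the perturbation epochs that drive D_r away from 0)
have no canonical functional form; they are modeled as an additive
forcing u(t) chosen so the unforced equation is recovered exactly at
u ≡ 0.  A step challenge uses u = a·A so that the dial `A` is the
steady-state deviation the challenge pulls toward; ramps rise linearly to
that level; impulses are an instantaneous velocity kick.

## Gain composition

Per-system gains combine as
κ = κ_BG^{w_BG} · κ_CTX^{w_CTX} · C(κ_CBL, κ_BG+CTX) with the log-linear
form as its exact logarithm.  The combined cortico–basal-ganglia gain
κ_BG+CTX is defined as the weight-normalized geometric mean
κ_BG^{w_BG}·κ_CTX^{w_CTX} — the unique definition that keeps the two
composition forms mutually consistent and dimensionless.

Weights are functions of the interval duration τ being timed.  We use a
logistic pair in log10(τ) for the cerebellar/basal-ganglia trade-off
(falling/rising, crossing at τ_cross, default 1 s — the conventional
sub-/supra-second boundary) plus a log-Gaussian cortical bump (center
log10(τ) = 0, width 0.5 decades, height 0.5), renormalized by their sum
so Σw = 1 holds exactly at every τ.  Because the logistic pair sums to 1
before renormalization and the bump divides all three equally, the
CBL/BG crossover survives renormalization at exactly τ_cross.  With the
default slope (2 per decade) the cerebellar weight is strictly
decreasing and the basal-ganglia weight strictly increasing everywhere,
which the tests verify on a log grid.  Whether the composition exponents
are constants or τ-dependent was an open choice; we evaluate the weights
at the task's interval duration, with plain tuples accepted anywhere a
weight triple is needed so constant overrides are trivial.

The comparator C is pluggable through a registry keyed by name; the
default form is C = κ_CBL^{w_CBL} · κ_BG+CTX^{−g}.  This is the simplest
form meeting the contract we impose on every registered comparator:
C(1, 1) = 1, and with a veridical cerebellar gain the composed |ln κ| is
non-increasing in the comparator strength g, with g = 1 restoring κ = 1
exactly.  The registry signature receives the weight triple as well, so
alternative forms may use it.

Composed κ is interpreted as the *instantaneous equilibrium* that the
restoring dynamics relax toward: scenarios integrate
D̈_r = −a(D_r − D_eq(t)) − b·Ḋ_r + u(t) with D_eq from the pointwise
composition.  This is an interpretation choice — the composition by
itself says nothing about transients — and it reduces to the plain
restoring equation when all component gains are neutral.

## Disorder presets and classification

Presets encode only the *sign* of ln κ per system; the magnitude δ
(default 0.2 on the ln scale, i.e. ±22%/−18% gains) is an explicit user
parameter.  "Unstable" entries are a seeded stationary Ornstein–Uhlenbeck
process on ln κ (mean 0, sd = `instability_sd`, correlation time 1 s):
temporal jitter requires a stochastic process, and a zero mean keeps the
regime distinct from dilation/compression.  Schizophrenia uses sd 0.2 on
its two unstable systems; ASD uses sd 0.35 on all three, reflecting its
broader multisystem desynchronization and giving the two regimes
separable fluctuation statistics.  Anxiety/PTSD accepts an optional
threat-epoch schedule during which its dilation bias applies; the default
is tonic (whole-run) bias.  Parkinsonism's scale dependence falls out of
the weights: the same preset (κ_CBL < 1, κ_BG, κ_CTX > 1) composes to
κ < 1 below 1 s and κ > 1 above it.

Scenario defaults: a critically damped fast regulator (a = 25, b = 10;
time constant 0.2 s), so the total gain tracks its composed equilibrium
faster than pathological fluctuations evolve, on a 60 s grid at 20 ms —
long enough to estimate fluctuation statistics over many OU correlation
times.

Classification thresholds (all exposed as keyword arguments):
dilated/compressed when the time-averaged D_r exceeds ±θ = 0.05;
"unstable" when the deviation flips sign at least 3 times among samples
with |D_r| > θ.  The precision level is "unstable" when std(ln κ) over
the run exceeds 0.12 (chosen between the fluctuation levels the two
unstable presets produce at their default sds), otherwise "low" when the
effective precision 1/mean|D_r| falls below 20 *or* the regime itself is
unstable — a sign-flipping deviation degrades timing precision even when
its average magnitude is modest — otherwise "normal".  The effective
precision replaces the mean instantaneous P, whose time average diverges
whenever the trajectory crosses κ = 1.

Interventions are parameter edits only (comparator gain, damping,
stiffness, or a component-gain shift), applied from an onset time after
which the scenario is re-simulated from its current state; no biophysical
stimulation model is attempted.

## Task forward models

*Reproduction.*  The gain transformation alone makes reproducing a
self-encoded interval gain-invariant, so encoding and readout gains are
kept explicit: the noiseless reproduction is (κ_enc/κ_rep)·Δt, with the
pathological state conventionally at encoding (κ_rep = 1) so a compressed
gain yields short reproductions.  Users can invert the convention by
swapping the arguments.

*Bisection.*  Probes are judged "long" when the subjective duration
κ·Δt exceeds the geometric mean of the anchors — the standard
parameter-free bisection criterion — with Gaussian judgment noise on the
log scale: P(long) = Φ((ln(κΔt) − ln B)/σ_ln), B = √(short·long).  The
objective 50% point is therefore B/κ: a dilated gain produces more "long"
judgments at every probe and a *lower* objective bisection point.  Note
that under the usual axis convention this is a leftward shift of the
objective psychometric function, although such a regime is sometimes
described as a rightward shift; the package implements the
"more long judgments" semantics and leaves the axis label to the user.
The psychometric fit is a probit GLM on log duration.

*Tapping.*  Continuation-phase inter-tap intervals are lognormal with
mean (κ_enc/κ_rep)·period and CV = cv0 + c·|D_r| (defaults cv0 = 0.05,
c = 0.5): variability rises as precision falls, with a motor/clock noise
floor keeping CV positive at perfect timing.

*EEG readout.*  Periods scale by κ, so spectral peaks scale by 1/κ.  The
synthetic spectrum is a unit-height Gaussian bump (default width 1 Hz) on
a weak 1/f background over a 1–40 Hz grid at 0.1 Hz, with additive
Gaussian noise clipped at zero.  Peak detection smooths with an 11-bin
(1.1 Hz) moving average — wide enough to suppress noise-induced argmax
jumps at the default noise level, symmetric so it does not bias a
symmetric peak — then refines the argmax by quadratic interpolation.

Duration noise is multiplicative lognormal with unit mean, so stated
means are exact at any noise level; noise magnitudes are package
defaults, not empirical claims.

## Inference

(a, b, D_r(0), Ḋ_r(0)) are fit by bounded least squares against the
closed-form solution across all damping branches, with 16 Latin-hypercube
starts (seeded) because the objective has branch-dependent local optima;
standard errors come from the Gauss–Newton curvature at the optimum.
Trajectories with max |D_r| < 1e−6 are flagged degenerate instead of
fitted — the zero trajectory solves the dynamics for every (a, b).  The
gain estimator for reproduction data is the geometric mean of
response/stimulus ratios (the lognormal MLE, matching the generator),
with a seeded 1000-resample percentile bootstrap CI.  The EEG estimator
is the algebraic inverse κ̂ = f_base/f_peak, so its accuracy is limited
by the spectral grid resolution.

## Synthetic data and what passing tests show

All observations the estimators consume are generated by the package's
own seeded forward models: lognormal duration noise, Bernoulli bisection
choices, Gaussian spectral noise, OU gain jitter.  They emulate the
*structure* of timing data (positive skewed durations, scalar-like CV,
unimodal spectra) but not real-data complications — sequential effects,
attention lapses, 1/f-dominated low-SNR spectra, drift in κ within a
session, or inter-individual parameter spread.  Recovery results
therefore demonstrate internal consistency (the estimators invert the
stated generators at the stated noise levels and sample sizes), not
field-readiness for clinical recordings.

## Problem sizes and numerical defaults

Default simulation horizons (10 s fits, 60 s scenarios), trial counts
(10⁴ for Monte-Carlo checks, 100–200 for recovery experiments, 20
replicates) and the RK4 step rule are chosen so every experiment in the
test suite is exactly reproducible from its seeds at desk scale.
Tolerances used in tests: 1e−12 for algebraic identities (composition
equivalence, change of variables, weight normalization), 1e−8 for
integrator-vs-closed-form agreement, Monte-Carlo tolerances (1–5%)
calibrated from the generators' known sampling variance.

## Known limitations

The restoring dynamics are linear and deterministic; stochasticity enters
only through observation noise and the OU gain paths, not the dynamics
themselves.  The comparator acts on time-averaged weights at a single
task duration per scenario.  Eyeblink-conditioning-style readouts are not
modeled (no generative mechanism specific enough to implement); no real
EEG ingestion or fitting to clinical data is provided, and presets carry
no diagnostic claim.
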