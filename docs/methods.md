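# Methods

## Model

The neuron is the two-variable FitzHugh–Nagumo (FN) system with a free
cubic coefficient,

    dV/dt = V − d·V³ − W + I(t)
    dW/dt = c·V + a − b·W,

read out as an instantaneous firing rate through a logistic sigmoid,
r(t) = F / (1 + exp(−V(t))). Time is in milliseconds, r and F in ms⁻¹,
and the stimulus amplitude is applied directly as the current I (µA as
printed in the study conditions, numerically unconverted). The parameter
vector is θ = [a, b, c, d, F]; all five are constrained non-negative.
The nominal (data-generating) values are a = 0.08, b = 0.056, c = 0.064,
d = 0.333, F = 100 ms⁻¹ (`fnspike.NOMINAL_PARAMS`).

Spiking is an inhomogeneous Poisson process (IPP) with intensity r(t):
history effects (refractoriness, bursting, adaptation) are deliberately
outside the model. Each trial starts from V(0) = W(0) = 0.

## Discretization

One fixed grid carries everything: integration, spike bins, and the
likelihood's integral. The window is Tf = 30 ms with dt = 0.01 ms (10 µs)
by default; nodes sit at the left endpoints 0, dt, …, Tf − dt. The ODE is
integrated by explicit forward Euler (first order, verified by step-halving
tests); the rate at node i is the sigmoid of the pre-step V_i, the
likelihood integral is the left Riemann sum Σ r_i·dt, and bin i of the
Bernoulli sampler fires with probability min(r_i·dt, 1). Tying the three
to one discretization makes the generative model and the estimator exactly
consistent with each other; the cost is O(r·dt) discretization bias common
to both, negligible at 10 µs. A classical Runge–Kutta (RK4) integrator is
available for step-size studies, but with the stimulus held constant over
each step (zero-order hold) it is first-order-limited for time-varying
input; its higher order materializes only for held (piecewise-constant)
stimuli.

Numerical guards: V is clamped to ±500 before exponentiation (exp stays
finite in float64 inside the clamp, so the rate is unchanged to machine
precision wherever the clamp is inactive); |V| or |W| exceeding 10⁶ is
treated as divergence — nominal trajectories stay O(10), so this
unambiguously flags a bad parameter draw. Divergence raises an error in
the simulation path and yields a −∞ log-likelihood sentinel (never NaN)
inside estimation, so bounded optimizers reject infeasible iterates
gracefully.

The hot paths (batch Euler integration and the joint log-likelihood with
its gradient) are numba-compiled kernels; a pure-numpy per-trial reference
path is public API and the test suite pins the two against each other to
≤ 10⁻⁹ relative.

## Stimulus

Each trial's current is a phased-cosine Fourier series
I(t) = Σₙ Amax·cos(2π·f0·n·t + φₙ), n = 1…NU, with a common component
amplitude Amax and base frequency f0 in kHz (so the phase argument is
dimensionless with t in ms). The phases are i.i.d. uniform on [−π, π],
drawn once per trial and stored with the trial, because the likelihood
must re-integrate the model under the same stimulus that elicited the
spikes. Defaults (the baseline study conditions): NU = 5, Amax = 100 µA,
f0 = 1/3 kHz, Nit = 100 trials. Swept values: Nit ∈ {25, 50, 100, 200},
NU ∈ {5, 10, 20, 30}, Amax ∈ {25, 50, 100, 200} µA,
f0 ∈ {1/3, 1, 5/3, 7/3} kHz.

## Spike sampling

Primary sampler: local Bernoulli — bin i fires iff min(r_i·dt, 1) exceeds
an independent U[0,1] draw; spike times are reported at the bin's left
node (no sub-bin jitter); at most one spike per bin. The clip at 1 is
explicit because F·dt = 1 at the defaults, so the bound is reachable; a
clipped bin logs a warning (the approximation, not the code, degrades).
Independent oracle: thinning — homogeneous Poisson candidates at a bound
r* (the trajectory maximum by default) kept with probability r(t)/r*, the
rate linearly interpolated between nodes. Both samplers target the same
IPP and the tests check count- and ISI-level agreement. Time-rescaling
simulation is not implemented; two independent routes suffice for
cross-validation. Every trial consumes its own spawned RNG substream, so
a dataset is exactly replayable from one master seed.

## Likelihood and estimator

Per trial, ℓ = −Σᵢ r_i·dt + Σₖ ln r at the spike's node; synthetic spikes
are snapped to the nearest node (error beyond dt/2 — only possible past
the final node), recorded spikes floor to the containing bin. Trials add
independently.

The ML estimate maximizes the joint ℓ over the box [0, 1]⁴ × [0, 200]
(zero lower bounds because all FN parameters are positive; upper bounds
enclose the nominal values with wide margin and are configurable) using
scipy's L-BFGS-B on internally rescaled coordinates θ/scale, scale =
(1, 1, 1, 1, 200), so all search directions are O(1). Two design choices
depart from the obvious defaults, both for optimizer reliability:

* **Exact gradients.** The gradient of the Euler-discretized objective is
  computed by forward sensitivity recursions propagated alongside the
  state (the sigmoid derivative is zeroed where the V clamp is active,
  and ∂ℓ/∂F = (K − λ)/F per trial). This is ~6× fewer objective sweeps
  than finite differences and, unlike them, exact for the discretized
  objective; finite differences remain available (`gradient="numeric"`)
  and serve as the test oracle.
* **Three random starts.** The likelihood has a shallow ridge in (a, b, c)
  — W barely moves within 30 ms, so these parameters are weakly
  identified — and single random starts occasionally converge to genuine
  local optima on it. Three uniform-in-bounds starts (best final value
  wins) removed every trap observed during development. The initial
  guess can also be supplied explicitly.

Tolerances: ftol 10⁻¹² (relative; the objective is O(10⁶), so anything
looser leaves F-precision worse than its sampling scatter), projected-
gradient tolerance 10⁻³ in scaled coordinates, 500 iterations maximum.
At the F = 0 boundary the likelihood is −∞ and K/F overflows; F is
floored at 10⁻¹² inside the objective so that boundary probes return
large-but-finite values the line search can back away from.

## The simulation study

A scenario fixes (Nit, NU, Amax, f0, Tf, dt, R, seed). One repetition
generates a fresh Nit-trial dataset at the nominal parameters and fits
it from fresh random starts; R repetitions give the per-parameter mean
and sample standard deviation (denominator R − 1) that populate the
recovery tables. Failed repetitions are excluded and counted, never
retried (silent retry would bias the dispersion downward); none occurred
in the committed runs. The repetition count behind a published cell is
not part of the study conditions; the package default is R = 50, the
acceptance runs use R = 30, and the amplitude-sweep trend check uses
R = 100 because adjacent-amplitude dispersion gaps (~18%) are smaller
than the ~13% Monte-Carlo noise of a standard deviation estimated from
30 values.

The relative-error diagnostic between consecutive cases of an ordered
estimate series is ER(k) = |θ̂(k) − θ̂(k−1)| / |θ̂(k−1)| (absolute values
throughout; a zero previous estimate yields an Inf sentinel unless the
estimate did not change, which yields 0).

## Long-recording pathway

A raw recording is a stimulus vector plus a binary spike indicator at a
fixed sampling interval (MATLAB workspace, NPZ and CSV dialects). It is
cut into equal segments (floor semantics, remainder dropped), each
treated as an independent trial; the recorded stimulus segment is used
directly as I(t), zero-order-held onto the integration grid, with a
configurable amplitude scale (default 1.0 — how a recorded stimulus maps
to model current is genuinely underdetermined, so the minimal choice is
the default). Incremental estimation fits growing prefixes ("first N
segments") and reports the ER series. Numerical results on the actual
blowfly H1 recording are not part of the test surface — the file must be
downloaded separately and its stimulus units and appropriate parameter
bounds are not determinable from the published analysis — but the entire
pathway runs, and is tested, on package-generated synthetic recordings.

## ISI validation

Model adequacy is checked distributionally: spike trains from reference
segments and from model simulations under the same stimuli are each
superimposed (train k offset by k × window), ISIs are taken on the merged
sequences, and a two-sample Kolmogorov–Smirnov test (asymptotic p-value,
via scipy) compares them as the number of superimposed segments grows.
Superimposing *before* ISI extraction means inter-segment gaps contribute
intervals; this mirrors the estimation-study procedure rather than a
statistically purer per-segment pooling, and is a known caveat. Null
calibration (independent simulations at identical parameters) and
separation (grossly different F) are covered by tests.

## Synthetic fixtures

All test inputs are generated programmatically: a baseline dataset at the
nominal parameters, and a miniature continuous recording — a
piecewise-constant Gaussian stimulus (sd 50 µA, 2 ms hold; values chosen
to drive V over a range comparable to the cosine stimuli) integrated at
the nominal parameters, Bernoulli-sampled, and collapsed to a binary
indicator at the recording's sampling interval. A bin containing more
than one spike still reads 1, so at coarse sampling the indicator
undercounts — tests that need lossless spike recovery sample the
indicator at the integration step. The fixture emulates the *shape* of a
real recording, not blowfly H1 statistics.

## What the synthetic conditions do and do not show

Passing tests demonstrate parameter recovery and calibrated dispersion
when the data truly come from the model: an FN-driven IPP, known
stimulus, exact trial alignment, no refractoriness, no adaptation, no
measurement jitter. They do not establish that a real neuron's spikes are
FN–Poisson, that recovery survives model mismatch, or that the recorded
stimulus's units map 1:1 onto model current. The KS pathway tests
distributional adequacy only — equality of ISI laws, not correctness of
the fitted mechanism.

## Known limitations

* a, b, c are weakly identified over 30 ms windows (the recovery tables'
  own dispersion shows this); their estimates can pin at the zero bound
  on individual datasets.
* The likelihood is non-convex; three starts removed all observed traps
  but global optimality is not guaranteed.
* Euler at 10 µs is first-order; halving dt changes estimates by far less
  than their sampling scatter, but very stiff parameter corners (large d
  with large |I|) are handled by the divergence sentinel rather than by
  adaptive stepping.
* The asymptotic KS p-value is used even at small segment counts, where
  it is approximate.
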