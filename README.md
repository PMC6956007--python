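# fnspike

Maximum-likelihood estimation of the parameters of a firing-rate
FitzHugh–Nagumo neuron from **spike timings alone** — discrete,
amplitude-free point-process data of the kind an extracellular electrode
delivers in vivo, where no membrane-potential trace is available for
conventional least-squares system identification.

## Who this is for

Computational neuroscientists and methods developers who want to fit a
mechanistic (rather than black-box) neuron model to spike trains, study
how stimulus design (amplitude, bandwidth, trial count) affects the
precision of the recovered parameters, or validate a fitted model against
recorded data through interspike-interval statistics.

## The model and the estimator

The neuron is a FitzHugh–Nagumo oscillator with a free cubic coefficient,
driven by an injected current *I(t)*:

    dV/dt = V − d·V³ − W + I(t)
    dW/dt = c·V + a − b·W

Instead of exposing *V*, the model emits an instantaneous firing rate
through a logistic readout with maximum rate *F* (ms⁻¹):

    r(t) = F / (1 + exp(−V(t)))

so that θ = [a, b, c, d, F] fully determines the stimulus → rate map.
Spikes are an inhomogeneous Poisson process with intensity *r(t)*; a
spike train t₁ < … < t_K observed on [0, T] therefore has log-likelihood

    ℓ(θ) = −∫₀ᵀ r(t; θ) dt + Σₖ ln r(tₖ; θ)

and *M* independently stimulated trials add their ℓ's. The ML estimate

    θ̂ = argmax_θ  Σₘ ℓₘ(θ),   θ ≥ 0

is computed by bounded L-BFGS-B with exact forward-sensitivity gradients
of the Euler-discretized objective (time step 10 µs by default, shared by
the integrator, the Bernoulli spike bins and the likelihood's Riemann sum).

The package also provides: phased-cosine Fourier stimuli with per-trial
random phases; two independent spike-train simulators (local Bernoulli
and thinning); the repeated-estimation simulation study that tabulates
the mean and standard deviation of θ̂ across stimulus scenarios; a
segmentation pathway for long recordings (e.g. the blowfly H1 archive's
MATLAB file) with incremental estimation over growing sample subsets and
a relative-error convergence diagnostic; and two-sample Kolmogorov–Smirnov
comparison of ISI distributions between reference and model-simulated
superimposed spike sequences.

## Worked example

```python
import numpy as np
import fnspike as fs

# 50 trials of 30 ms at the nominal parameters
# theta = [0.08, 0.056, 0.064, 0.333, 100]
sc = fs.Scenario(nit=50, nu=5, amax=100.0, f0=1/3, seed=42)
ds = fs.generate_dataset(fs.NOMINAL_PARAMS, sc, np.random.default_rng(42))
print(len(ds), ds.total_spikes)        # 50 73464

res = fs.estimate(ds, seed=0)
print({k: round(v, 4) for k, v in res.params.to_dict().items()})
# {'a': 0.0815, 'b': 0.0384, 'c': 0.0394, 'd': 0.3312, 'F': 99.9247}
print(round(res.log_likelihood, 2))    # 257855.05
print(round(fs.joint_log_likelihood(ds, fs.NOMINAL_PARAMS), 2))  # 257854.28
```

Fifty 30-ms trials carry ~73k spikes, and the fit lands on top of the
generating parameters for the strongly identified coordinates (*d* to
0.6%, *F* to 0.08%), while *a*, *b*, *c* scatter more — their likelihood
ridge is shallow, which is exactly what the repeated-estimation study
quantifies. The fitted log-likelihood slightly exceeds the value at the
generating parameters, as it must for an exact maximizer on one finite
dataset.

The same operations are scriptable from a shell:

```sh
fnspike simulate --config scenario.yaml --out data/
fnspike estimate --data data/ --out est.json
fnspike sweep --grid grid.yaml --out tables/
fnspike relerr --estimates est_series.csv
```

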