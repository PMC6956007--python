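"""Numba fast paths for batch Euler integration and the joint log-likelihood.

These kernels duplicate, loop-for-loop, the reference numpy implementations
in :mod:`fnspike.model` and :mod:`fnspike.likelihood`; the test suite pins
the two routes against each other.  All kernels share the conventions:

* state starts at (V, W) = (0, 0) at node 0;
* the rate at node i is the sigmoid of V_i (clamped at +-v_clip), so the
  left-Riemann integral and the per-spike log-rate terms both read the
  pre-step state;
* divergence (|V| or |W| > blowup, or non-finite) is reported, never raised,
  so the optimizer can treat the iterate as infeasible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def integrate_rates(a, b, c, d, F, stim, dt, v_clip, blowup):
    """Euler rate trajectories for M trials; returns (rates, bad_step).

    ``stim`` is (M, n).  ``bad_step`` is -1 on success, else the step index
    at which the first trial diverged.
    """
    M, n = stim.shape
    rates = np.empty((M, n))
    for m in range(M):
        V = 0.0
        W = 0.0
        for i in range(n):
            x = V
            if x > v_clip:
                x = v_clip
            elif x < -v_clip:
                x = -v_clip
            rates[m, i] = F / (1.0 + np.exp(-x))
            dV = V - d * V * V * V - W + stim[m, i]
            dW = c * V + a - b * W
            V += dt * dV
            W += dt * dW
            if not (np.isfinite(V) and np.isfinite(W)) or abs(V) > blowup or abs(W) > blowup:
                return rates, i
    return rates, -1


@njit(cache=True)
def joint_loglik(a, b, c, d, F, stim, dt, spk_flat, spk_off, v_clip, blowup):
    """Joint log-likelihood over M trials.

    ``spk_flat`` holds the spike node indices of all trials concatenated
    (each trial's block ascending); ``spk_off`` (length M+1) delimits the
    blocks.  Returns -inf on divergence or a zero rate at a spike node.
    """
    M, n = stim.shape
    total = 0.0
    for m in range(M):
        V = 0.0
        W = 0.0
        ptr = spk_off[m]
        end = spk_off[m + 1]
        acc = 0.0
        logs = 0.0
        for i in range(n):
            x = V
            if x > v_clip:
                x = v_clip
            elif x < -v_clip:
                x = -v_clip
            r = F / (1.0 + np.exp(-x))
            acc += r
            while ptr < end and spk_flat[ptr] == i:
                if r <= 0.0:
                    return NEG_INF
                logs += np.log(r)
                ptr += 1
            dV = V - d * V * V * V - W + stim[m, i]
            dW = c * V + a - b * W
            V += dt * dV
            W += dt * dW
            if not (np.isfinite(V) and np.isfinite(W)) or abs(V) > blowup or abs(W) > blowup:
                return NEG_INF
        total += -acc * dt + logs
    return total


@njit(cache=True)
def joint_loglik_grad(a, b, c, d, F, stim, dt, spk_flat, spk_off, v_clip, blowup):
    """Joint log-likelihood and its exact gradient wrt (a, b, c, d, F).

    The gradient is the derivative of the Euler-discretized objective
    itself, propagated through the state recursion by forward sensitivity:

        sV_{i+1} = sV_i + dt * ((1 - 3 d V_i^2) sV_i - sW_i - [p=d] V_i^3)
        sW_{i+1} = sW_i + dt * (c sV_i - b sW_i + [p=a] - [p=b] W_i + [p=c] V_i)

    with dr/dV = F s (1 - s) (zero where the V clamp is active) and
    dl/dF = (K - lambda)/F per trial.  Returns (ll, grad); ll = -inf with a
    zero gradient marks an infeasible parameter point.
    """
    M, n = stim.shape
    grad = np.zeros(5)
    total = 0.0
    sV = np.empty(4)
    sW = np.empty(4)
    acc_s = np.empty(4)
    log_s = np.empty(4)
    for m in range(M):
        V = 0.0
        W = 0.0
        for p in range(4):
            sV[p] = 0.0
            sW[p] = 0.0
            acc_s[p] = 0.0
            log_s[p] = 0.0
        ptr = spk_off[m]
        end = spk_off[m + 1]
        n_spikes = end - ptr
        acc = 0.0
        logs = 0.0
        for i in range(n):
            x = V
            inside = True
            if x > v_clip:
                x = v_clip
                inside = False
            elif x < -v_clip:
                x = -v_clip
                inside = False
            s = 1.0 / (1.0 + np.exp(-x))
            r = F * s
            acc += r
            if inside:
                drdv = F * s * (1.0 - s)
                for p in range(4):
                    acc_s[p] += drdv * sV[p]
            while ptr < end and spk_flat[ptr] == i:
                if r <= 0.0:
                    return NEG_INF, np.zeros(5)
                logs += np.log(r)
                if inside:
                    one_minus_s = 1.0 - s
                    for p in range(4):
                        log_s[p] += one_minus_s * sV[p]
                ptr += 1
            V3 = V * V * V
            dV = V - d * V3 - W + stim[m, i]
            dW = c * V + a - b * W
            jac_vv = 1.0 - 3.0 * d * V * V
            for p in range(4):
                ext_v = -V3 if p == 3 else 0.0
                if p == 0:
                    ext_w = 1.0
                elif p == 1:
                    ext_w = -W
                elif p == 2:
                    ext_w = V
                else:
                    ext_w = 0.0
                nsV = sV[p] + dt * (jac_vv * sV[p] - sW[p] + ext_v)
                nsW = sW[p] + dt * (c * sV[p] - b * sW[p] + ext_w)
                sV[p] = nsV
                sW[p] = nsW
            V += dt * dV
            W += dt * dW
            if not (np.isfinite(V) and np.isfinite(W)) or abs(V) > blowup or abs(W) > blowup:
                return NEG_INF, np.zeros(5)
        total += -acc * dt + logs
        lam = acc * dt
        for p in range(4):
            grad[p] += -acc_s[p] * dt + log_s[p]
        grad[4] += (n_spikes - lam) / F
    return total, grad
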