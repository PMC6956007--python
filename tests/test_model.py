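"""FN vector field, sigmoid rate map, and fixed-step integration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import fsolve

import fnspike as fs
from fnspike.errors import (
    IntegrationDivergedError,
    InvalidInputError,
    InvalidParameterError,
    InvalidStateError,
)

TABLE = fs.NOMINAL_PARAMS


class TestDerivatives:
    @pytest.mark.parametrize(
        "state,params,stim,expected",
        [
            ((0.0, 0.0), TABLE, 0.0, (0.0, 0.08)),
            ((1.0, 0.0), fs.NeuronParams(0, 0, 0, 0, 1.0), 0.0, (1.0, 0.0)),
            ((2.0, 1.0), TABLE, 0.5, (-1.164, 0.152)),
        ],
    )
    def test_hand_evaluations(self, state, params, stim, expected):
        dv, dw = fs.fn_derivatives(fs.NeuronState(*state), params, stim)
        assert dv == pytest.approx(expected[0], abs=1e-12)
        assert dw == pytest.approx(expected[1], abs=1e-12)

    def test_agrees_with_symbolic_form(self):
        """Cross-check against a sympy-lambdified copy of the vector field."""
        import sympy as sp

        V, W, a, b, c, d, I = sp.symbols("V W a b c d I")
        fV = sp.lambdify((V, W, a, b, c, d, I), V - d * V**3 - W + I)
        fW = sp.lambdify((V, W, a, b, c, d, I), c * V + a - b * W)
        rng = np.random.default_rng(7)
        for _ in range(1000):
            v, w, i_ext = rng.normal(0, 3, 3)
            pa, pb, pc, pd = rng.uniform(0, 1, 4)
            params = fs.NeuronParams(pa, pb, pc, pd, 50.0)
            dv, dw = fs.fn_derivatives(fs.NeuronState(v, w), params, i_ext)
            assert dv == pytest.approx(fV(v, w, pa, pb, pc, pd, i_ext), rel=1e-14, abs=1e-14)
            assert dw == pytest.approx(fW(v, w, pa, pb, pc, pd, i_ext), rel=1e-14, abs=1e-14)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(InvalidStateError):
            fs.NeuronState(float("nan"), 0.0)
        with pytest.raises(InvalidStateError):
            fs.fn_derivatives(fs.NeuronState(0, 0), TABLE, float("inf"))
        with pytest.raises(InvalidParameterError):
            fs.NeuronParams(-0.1, 0, 0, 0, 1.0)
        with pytest.raises(InvalidParameterError):
            fs.NeuronParams(0.1, 0, 0, 0, 0.0)


class TestFiringRate:
    def test_midpoint_saturation_and_quartile(self):
        assert fs.firing_rate(0.0, 100.0) == pytest.approx(50.0, abs=1e-12)
        assert fs.firing_rate(40.0, 100.0) == pytest.approx(100.0, rel=1e-15)
        assert fs.firing_rate(-math.log(3), 100.0) == pytest.approx(25.0, rel=1e-12)

    def test_monotone_and_bounded(self):
        v = np.linspace(-600, 600, 4001)
        r = fs.firing_rate(v, 100.0)
        assert np.all(np.diff(r) >= 0)
        assert np.all(r > 0) and np.all(r <= 100.0)
        # strictly below F wherever the clamp cannot saturate the sigmoid
        inside = np.abs(v) < 30
        assert np.all(r[inside] < 100.0)


class TestTimeGrid:
    def test_node_count_and_times(self):
        g = fs.TimeGrid(30.0, 0.01)
        assert g.n_nodes == 3000
        assert g.times[0] == 0.0
        assert g.times[-1] == pytest.approx(30.0 - 0.01)

    def test_non_multiple_rejected(self):
        with pytest.raises(InvalidInputError):
            fs.TimeGrid(30.0, 0.007)


class TestIntegration:
    def test_constant_rate_at_equilibrium(self):
        """Started at an equilibrium (root-solved independently), the rate
        trajectory stays constant up to Euler drift."""
        params = fs.NeuronParams(a=0.0, b=0.1, c=0.05, d=0.333, F=100.0)

        def field(x):
            dv, dw = fs.fn_derivatives(fs.NeuronState(*x), params, 0.0)
            return [dv, dw]

        eq = fsolve(field, x0=[1.5, 0.5], full_output=False)
        assert np.linalg.norm(field(eq)) < 1e-10
        assert abs(eq[0]) > 0.5  # non-trivial equilibrium
        grid = fs.TimeGrid(30.0, 0.01)
        rate = fs.integrate_rate(
            params, np.zeros(grid.n_nodes), grid, fs.NeuronState(*eq)
        )
        r_eq = fs.firing_rate(eq[0], params.F)
        assert np.max(np.abs(rate.values - r_eq)) < 1e-6

    def test_rate_strictly_inside_range(self, default_grid):
        rng = np.random.default_rng(3)
        spec = fs.random_stimulus(5, 100.0, 1 / 3, rng)
        rate = fs.integrate_rate(TABLE, spec.waveform(default_grid), default_grid)
        assert np.all(rate.values > 0)
        assert np.all(rate.values < TABLE.F)

    def test_first_order_convergence(self):
        """Halving dt roughly halves the error against a fine reference."""
        tf = 2.0
        stim_fn = lambda t: 50.0 * np.cos(2 * np.pi * t / 3)
        ref_grid = fs.TimeGrid(tf, 1e-4)
        v_ref, _ = fs.integrate_states(TABLE, stim_fn(ref_grid.times), ref_grid)
        t_probe = 1.99
        errors = []
        for dt in (0.01, 0.005, 0.0025):
            g = fs.TimeGrid(tf, dt)
            v, _ = fs.integrate_states(TABLE, stim_fn(g.times), g)
            i = int(round(t_probe / dt))
            i_ref = int(round(t_probe / 1e-4))
            errors.append(abs(v[i] - v_ref[i_ref]))
        r1 = errors[0] / errors[1]
        r2 = errors[1] / errors[2]
        assert 1.5 < r1 < 2.7
        assert 1.5 < r2 < 2.7

    def test_rk4_more_accurate_than_euler_for_held_stimulus(self):
        # constant stimulus, where the zero-order hold is exact and RK4's
        # higher order shows (with varying stimulus both methods are limited
        # to first order by the per-step hold)
        tf = 2.0
        ref_grid = fs.TimeGrid(tf, 1e-4)
        v_ref, _ = fs.integrate_states(TABLE, np.full(ref_grid.n_nodes, 50.0), ref_grid)
        g = fs.TimeGrid(tf, 0.01)
        v_eu, _ = fs.integrate_states(TABLE, np.full(g.n_nodes, 50.0), g, method="euler")
        v_rk, _ = fs.integrate_states(TABLE, np.full(g.n_nodes, 50.0), g, method="rk4")
        i, i_ref = int(1.99 / 0.01), int(1.99 / 1e-4)
        assert abs(v_rk[i] - v_ref[i_ref]) < abs(v_eu[i] - v_ref[i_ref]) / 10

    def test_batch_matches_single_trial(self, default_grid):
        rng = np.random.default_rng(11)
        waveforms = np.stack(
            [fs.random_stimulus(5, 100.0, 1 / 3, rng).waveform(default_grid) for _ in range(4)]
        )
        batch = fs.integrate_rate_batch(TABLE, waveforms, default_grid)
        for m in range(4):
            single = fs.integrate_rate(TABLE, waveforms[m], default_grid)
            np.testing.assert_allclose(batch[m], single.values, rtol=1e-12)

    def test_divergence_raises_with_step_index(self, default_grid):
        runaway = fs.NeuronParams(0.0, 0.0, 0.0, 0.0, 100.0)
        stim = np.full(default_grid.n_nodes, 10.0)
        with pytest.raises(IntegrationDivergedError) as exc:
            fs.integrate_states(runaway, stim, default_grid)
        assert exc.value.step > 0
        with pytest.raises(IntegrationDivergedError):
            fs.integrate_rate_batch(runaway, stim[None, :], default_grid)

    @given(
        a=st.floats(0, 1), b=st.floats(0, 1), c=st.floats(0, 1),
        d=st.floats(0.05, 1), f_max=st.floats(1, 200), amp=st.floats(0, 200),
        seed=st.integers(0, 2**16),
    )
    def test_rate_bounds_hold_on_random_draws(self, a, b, c, d, f_max, amp, seed):
        params = fs.NeuronParams(a, b, c, d, f_max)
        grid = fs.TimeGrid(6.0, 0.01)
        spec = fs.random_stimulus(3, amp, 1.0, np.random.default_rng(seed))
        rate = fs.integrate_rate(params, spec.waveform(grid), grid)
        assert np.all(rate.values > 0)
        assert np.all(rate.values <= f_max)
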