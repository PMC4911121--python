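import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgsc.meanfield import (
    AlphaCurve,
    BracketingError,
    GridMismatchError,
    InstabilityError,
    MeanFieldCircuit,
    PulseSchedule,
    RangeError,
    alpha_of,
    eta_from_alpha,
    eta_solution_shape,
    find_S_exact,
    fit_meanfield,
    layer_gain,
    propagate_window,
    s_exact_curve,
    simulate_meanfield,
)


class TestPulseSchedule:
    def test_derived_quantities(self):
        s = PulseSchedule(T=0.0075, T0=0.003, tau=0.005)
        assert s.eta == pytest.approx(2.5)
        assert s.n == 2
        assert s.T1 == pytest.approx(0.0015)
        assert s.T == pytest.approx(s.n * s.T0 + s.T1)

    def test_validation(self):
        with pytest.raises(ValueError):
            PulseSchedule(T=-1.0, T0=0.5, tau=0.005)
        with pytest.raises(ValueError):
            PulseSchedule(T=0.01, T0=0.02, tau=0.005)  # T0 > T
        with pytest.raises(ValueError):
            PulseSchedule(T=0.01, T0=0.005, tau=0.0)

    @given(eta=st.floats(min_value=1.0, max_value=5.0),
           t0r=st.floats(min_value=0.1, max_value=2.0))
    @settings(max_examples=50, deadline=None)
    def test_invariants_random(self, eta, t0r):
        eta = round(eta, 3)  # rational overlap, as constructed in practice
        s = PulseSchedule.from_ratios(t0r, eta)
        assert s.eta >= 1.0 - 1e-12
        assert -1e-15 <= s.T1 < s.T0
        assert s.T == pytest.approx(s.n * s.T0 + s.T1, abs=1e-12)

    def test_grid_step_divides(self):
        s = PulseSchedule.from_ratios(0.6, 2.5)
        dt = s.grid_step()
        k0, kT = s.steps(dt)
        assert abs(k0 * dt - s.T0) < 1e-9
        assert abs(kT * dt - s.T) < 1e-9

    def test_integer_eta_degenerate(self):
        s = PulseSchedule.from_ratios(0.6, 3.0)
        assert s.n == 3
        assert s.T1 == pytest.approx(0.0, abs=1e-12)

    def test_serialization_roundtrip(self):
        s = PulseSchedule(T=0.0075, T0=0.003, tau=0.005)
        assert PulseSchedule.from_dict(s.to_dict()) == s


class TestPropagateWindow:
    def test_zero_input(self, sched_fig2):
        w = eta_solution_shape(sched_fig2).scaled(0.0)
        out = propagate_window(w, sched_fig2, S=1.582)
        assert np.all(out.values == 0.0)

    def test_zero_coupling(self, sched_fig2):
        w = eta_solution_shape(sched_fig2)
        out = propagate_window(w, sched_fig2, S=0.0)
        assert np.all(out.values == 0.0)

    def test_unit_gain_at_published_coupling(self, sched_fig2):
        # converge to the invariant waveform, then one more application
        _, shape = layer_gain(sched_fig2, 1.582, return_shape=True)
        out = propagate_window(shape, sched_fig2, 1.582)
        assert out.amplitude / shape.amplitude == pytest.approx(1.0, abs=1e-2)

    def test_linearity_machine_precision(self, sched_fig2):
        w = eta_solution_shape(sched_fig2)
        a = 3.7
        out1 = propagate_window(w.scaled(a), sched_fig2, 1.3)
        out2 = propagate_window(w, sched_fig2, 1.3)
        np.testing.assert_allclose(out1.values, a * out2.values, rtol=1e-13)

    def test_tail_invariant(self, sched_fig2):
        w = eta_solution_shape(sched_fig2)
        out = propagate_window(w, sched_fig2, 1.0)
        assert out.tail_is_exponential(sched_fig2.tau)

    def test_grid_mismatch_error(self, sched_fig2):
        w = eta_solution_shape(sched_fig2)
        other = PulseSchedule.from_ratios(0.6, 2.0)
        with pytest.raises(GridMismatchError):
            propagate_window(w, other, 1.0)

    def test_negative_coupling_allowed(self, sched_fig2):
        w = eta_solution_shape(sched_fig2)
        out = propagate_window(w, sched_fig2, -1.0)
        assert out.values.min() < 0
        assert out.tail_is_exponential(sched_fig2.tau)


class TestLayerGain:
    def test_zero_coupling(self, sched_fig2):
        assert layer_gain(sched_fig2, 0.0) == 0.0

    def test_published_unit_gain(self, sched_fig2):
        assert layer_gain(sched_fig2, 1.582) == pytest.approx(1.0, abs=1e-2)

    def test_monotone_in_S(self, sched_fig2):
        gains = [layer_gain(sched_fig2, S)
                 for S in np.arange(0.5, 3.01, 0.5)]
        assert np.all(np.diff(gains) > 0)

    def test_gain_brackets_unity(self, sched_fig2):
        s_star = find_S_exact(sched_fig2).S
        assert layer_gain(sched_fig2, 0.9 * s_star) < 1.0
        assert layer_gain(sched_fig2, 1.1 * s_star) > 1.0

    def test_fixed_point_12_layers(self, sched_fig2):
        """12 successive transfers at S_exact drift by < 3% cumulative."""
        s_star = find_S_exact(sched_fig2).S
        w = eta_solution_shape(sched_fig2)
        amps = [w.amplitude]
        for _ in range(12):
            w = propagate_window(w, sched_fig2, s_star)
            amps.append(w.amplitude)
        assert abs(amps[-1] / amps[1] - 1.0) < 0.03


class TestFindSExact:
    def test_published_anchor(self, sched_fig2):
        op = find_S_exact(sched_fig2)
        assert op.S == pytest.approx(1.582, abs=0.005)

    @pytest.mark.parametrize("t0r", [0.3, 0.6, 1.0])
    def test_eta1_closed_form(self, t0r):
        # at eta = 1 the exact coupling is exp(T0/tau)/(T0/tau)
        sched = PulseSchedule.from_ratios(t0r, 1.0)
        op = find_S_exact(sched, bracket=(0.05, 30.0))
        assert op.S == pytest.approx(math.exp(t0r) / t0r, rel=1e-3)
        assert op.alpha == pytest.approx(1.0, abs=1e-3)

    def test_bracketing_error(self, sched_fig2):
        with pytest.raises(BracketingError):
            find_S_exact(sched_fig2, bracket=(2.0, 3.5))

    def test_dt_refinement(self, sched_fig2):
        dt = sched_fig2.grid_step()
        s1 = find_S_exact(sched_fig2, dt=dt, tol=1e-5).S
        s2 = find_S_exact(sched_fig2, dt=dt / 2, tol=1e-5).S
        assert abs(s1 - s2) < 1e-4


class TestSExactCurve:
    @pytest.fixture(scope="class")
    def curve(self):
        etas = [1.0, 1.2, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        return s_exact_curve(0.6, etas)

    def test_alpha_one_at_eta_one(self, curve):
        assert curve[0].alpha == pytest.approx(1.0, abs=1e-3)

    def test_alpha_monotone_decreasing(self, curve):
        alphas = [p.alpha for p in curve]
        assert np.all(np.diff(alphas) < 0)

    def test_flattening(self, curve):
        etas = np.array([p.eta for p in curve])
        s = np.array([p.S for p in curve])
        slope = np.abs(np.diff(s) / np.diff(etas))
        i_low = np.argmin(np.abs(etas[:-1] - 1.2))
        i_high = np.argmin(np.abs(etas[:-1] - 3.0))
        assert slope[i_high] < slope[i_low]

    def test_finite_everywhere(self, curve):
        assert all(np.isfinite([p.S, p.alpha]) .all() for p in curve)

    def test_rejects_eta_below_one(self):
        with pytest.raises(ValueError):
            s_exact_curve(0.6, [0.8])


class TestAlphaOf:
    def test_zero(self):
        assert alpha_of(0.0, 0.003, 0.005) == 0.0

    def test_published_point(self):
        assert alpha_of(1.582, 0.003, 0.005) == pytest.approx(
            1.582 * 0.6 * math.exp(-0.6), rel=1e-12)
        assert alpha_of(1.582, 0.003, 0.005) == pytest.approx(0.5209, abs=1e-3)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            alpha_of(1.0, 0.003, 0.0)


class TestSimulateMeanfield:
    def test_no_pulses_no_rates(self):
        c = MeanFieldCircuit(n_pops=3, K=np.eye(3), S=2.0)
        t, I, m = simulate_meanfield(c, duration=0.05)
        assert np.all(m == 0.0)
        assert np.all(I == 0.0)

    def test_decay_without_input(self):
        c = MeanFieldCircuit(n_pops=2, K=np.eye(2), S=1.0)
        t, I, m = simulate_meanfield(c, duration=0.05,
                                     I0=np.array([10.0, 5.0]))
        assert np.all(I[:, -1] < 1e-3)

    def test_chain_amplitude_preserved_at_s_exact(self, sched_fig2):
        """Multi-layer gated chain settles to unit layer-to-layer gain."""
        s_star = find_S_exact(sched_fig2).S
        n = 7
        K = np.diag(np.ones(n - 1), -1)  # feedforward chain
        T0, T = sched_fig2.T0, sched_fig2.T
        pulses = [[(j * T0, j * T0 + T)] for j in range(n)]
        shape = eta_solution_shape(sched_fig2)

        def drive(t):
            d = np.zeros(n)
            d[0] = 30.0 * np.interp(t + T0, shape.times, shape.values)
            return d

        c = MeanFieldCircuit(n_pops=n, K=K, S=s_star, pulses=pulses,
                             drive=drive, tau=sched_fig2.tau)
        t, I, m = simulate_meanfield(c, duration=(n + 2) * T0 + 3 * T)
        amps = [I[j].max() for j in range(1, n)]
        assert amps[-1] / amps[-2] == pytest.approx(1.0, abs=1e-2)

    def test_active_linear_map(self, sched_fig2):
        """One gated transfer applies K to the vector of amplitudes."""
        K4 = np.array([[0.5, 0.2, 0.0, 0.1],
                       [0.0, 0.4, 0.3, 0.0],
                       [0.2, 0.0, 0.6, 0.2],
                       [0.1, 0.1, 0.0, 0.5]])
        n = 8
        K = np.zeros((n, n))
        K[4:, :4] = K4
        T0, T = sched_fig2.T0, sched_fig2.T
        pulses = [[(0.0, T)]] * 4 + [[(T0, T0 + T)]] * 4
        shape = eta_solution_shape(sched_fig2)
        x = np.array([20.0, 35.0, 10.0, 28.0])

        def drive(t):
            d = np.zeros(n)
            d[:4] = x * np.interp(t + T0, shape.times, shape.values)
            return d

        s_star = find_S_exact(sched_fig2).S
        c = MeanFieldCircuit(n_pops=n, K=K, S=s_star, pulses=pulses,
                             drive=drive, tau=sched_fig2.tau)
        t, I, m = simulate_meanfield(c, duration=T0 + T + 5 * sched_fig2.tau)
        up = np.array([I[j].max() for j in range(4)])
        down = np.array([I[j].max() for j in range(4, 8)])
        expected = K4 @ up
        np.testing.assert_allclose(down, expected, rtol=0.03)

    def test_instability_error(self):
        c = MeanFieldCircuit(n_pops=2, K=np.array([[5.0, 5.0], [5.0, 5.0]]),
                             S=10.0, pulses=[[(0.0, 1.0)], [(0.0, 1.0)]],
                             drive=lambda t: np.array([100.0, 100.0]))
        with pytest.raises(InstabilityError) as ei:
            simulate_meanfield(c, duration=1.0)
        assert ei.value.population in (0, 1)

    def test_dt_bound(self):
        c = MeanFieldCircuit(n_pops=1, K=np.zeros((1, 1)), S=0.0)
        with pytest.raises(ValueError):
            simulate_meanfield(c, duration=0.01, dt=c.tau / 10)


class TestFitMeanfield:
    @pytest.fixture(scope="class")
    def synthetic_traces(self, sched_fig2):
        """Traces generated from the invariant-waveform family itself."""
        eta_true, alpha_true = 2.5, 0.55
        T0, tau = sched_fig2.T0, sched_fig2.tau
        dt = 1e-4
        gain1, shape = layer_gain(sched_fig2, 1.0, return_shape=True,
                                  dt=sched_fig2.grid_step())
        g = alpha_true * math.exp(T0 / tau) / (T0 / tau) * gain1
        n_layers, n_t = 5, 800
        t = np.arange(n_t) * dt
        traces = np.zeros((3, n_layers, n_t))
        for i, a in enumerate([20.0, 35.0, 50.0]):
            for j in range(n_layers):
                traces[i, j] = a * g ** j * np.interp(
                    t - 0.005 - j * T0, shape.times, shape.values,
                    left=0.0, right=0.0)
        return traces, dt, (eta_true, alpha_true)

    def test_parameter_recovery(self, synthetic_traces, sched_fig2):
        traces, dt, (eta_true, alpha_true) = synthetic_traces
        eta_fit, alpha_fit, fitted, res = fit_meanfield(
            traces, T0=sched_fig2.T0, tau=sched_fig2.tau, dt=dt,
            layer0_onset=0.005)
        assert eta_fit == pytest.approx(eta_true, rel=0.02)
        assert alpha_fit == pytest.approx(alpha_true, rel=0.02)

    def test_scale_invariance(self, synthetic_traces, sched_fig2):
        traces, dt, _ = synthetic_traces
        f1 = fit_meanfield(traces, T0=sched_fig2.T0, tau=sched_fig2.tau,
                           dt=dt, layer0_onset=0.005)
        f2 = fit_meanfield(7.3 * traces, T0=sched_fig2.T0,
                           tau=sched_fig2.tau, dt=dt, layer0_onset=0.005)
        assert f1[0] == pytest.approx(f2[0], rel=1e-3)
        assert f1[1] == pytest.approx(f2[1], rel=1e-3)


class TestEtaFromAlpha:
    @pytest.fixture(scope="class")
    def curve(self):
        return AlphaCurve(0.6, eta_grid=np.r_[1.0, np.arange(1.1, 4.01, 0.1)])

    def test_alpha_one_maps_to_eta_one(self, curve):
        assert eta_from_alpha(1.0, 0.6, curve=curve) == pytest.approx(1.0,
                                                                      abs=1e-3)

    def test_round_trip(self, curve):
        for eta in (1.3, 2.0, 3.1):
            a = curve.alpha_at(eta)
            assert curve.eta_at(a) == pytest.approx(eta, abs=1e-3)

    def test_out_of_range(self, curve):
        with pytest.raises(RangeError):
            eta_from_alpha(curve.alpha.min() / 2, 0.6, curve=curve)
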