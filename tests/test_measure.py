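"""Curve fitting and derived measurements: Boltzmann, exponentials, envelopes."""

import numpy as np
import pytest

from hergkin import (
    FitError,
    ValidationError,
    activation_envelope_curve,
    boltzmann_fit,
    deactivation_time_constants,
    exp_fit,
    inactivation_exchange_time,
    iv_relationship,
    make_deactivation_protocol,
    make_envelope_protocol,
    make_ssa_protocol,
    recovery_time_constant,
    make_recovery_protocol,
    simulate_sweeps,
    ssa_activation_curve,
)


class TestBoltzmannFit:
    def test_recovers_noiseless_parameters(self):
        V = np.arange(-100.0, 41.0, 10.0)
        y = 1.0 / (1.0 + np.exp((-10.7 - V) / 8.1))
        fit = boltzmann_fit(V, y)
        assert fit.v_half == pytest.approx(-10.7, abs=1e-6)
        assert fit.slope == pytest.approx(8.1, abs=1e-6)
        assert fit.residual_norm < 1e-10

    def test_half_maximum_at_v_half(self):
        V = np.arange(-80.0, 41.0, 10.0)
        y = 1.0 / (1.0 + np.exp((-20.0 - V) / 9.0))
        fit = boltzmann_fit(V, y)
        assert fit(fit.v_half) == pytest.approx(0.5, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            boltzmann_fit([0.0, 1.0, 2.0], [0.1, 0.5, 0.9])

    def test_simulated_activation_half_voltage(self, m1, p1a, room_cp):
        traces = simulate_sweeps(m1, p1a, make_ssa_protocol(), cp=room_cp)
        V, y = ssa_activation_curve(traces)
        fit = boltzmann_fit(V, y)
        assert fit.v_half == pytest.approx(-10.7, abs=3.0)


class TestExpFit:
    def test_single_exponential_exact_recovery(self):
        t = np.arange(0.0, 100.0, 0.1)
        y = 2.5 * np.exp(-t / 10.0) + 0.3
        fit = exp_fit(t, y, n_components=1)
        assert fit.taus[0] == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(2.5, rel=1e-6)
        assert fit.offset == pytest.approx(0.3, abs=1e-6)

    def test_double_exponential_with_mild_noise(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 300.0, 0.1)
        amp = 0.7 * np.exp(-t / 5.0) + 0.3 * np.exp(-t / 50.0)
        y = amp + rng.normal(0.0, 0.001, t.size)  # noise SD 0.1% of amplitude
        fit = exp_fit(t, y, n_components=2)
        assert fit.tau_fast == pytest.approx(5.0, rel=0.01)
        assert fit.tau_slow == pytest.approx(50.0, rel=0.01)
        assert fit.amplitudes[0] == pytest.approx(0.7, rel=0.01)
        assert fit.amplitudes[1] == pytest.approx(0.3, rel=0.01)

    def test_components_ordered_fast_first(self):
        t = np.arange(0.0, 500.0, 0.5)
        y = 0.2 * np.exp(-t / 80.0) + 0.8 * np.exp(-t / 8.0)
        fit = exp_fit(t, y, n_components=2)
        assert fit.tau_fast < fit.tau_slow

    def test_degenerate_window_rejected(self):
        with pytest.raises(FitError):
            exp_fit(np.array([0.0, 1.0]), np.array([1.0, 0.5]), n_components=2)

    def test_b_isoform_deactivates_faster_at_minus_100(self, m1, p1a, p1b):
        prot = make_deactivation_protocol([-100.0])
        taus = {}
        for iso, params in (("a", p1a), ("b", p1b)):
            (tr,) = simulate_sweeps(m1, params, prot, sample_dt=0.5)
            tau_x = inactivation_exchange_time(params, -100.0)
            taus[iso] = deactivation_time_constants(
                tr, skip_ms=3.0 * tau_x, tau_min=3.0 * tau_x
            )
        assert taus["b"].tau_fast < taus["a"].tau_fast
        assert taus["b"].tau_slow < taus["a"].tau_slow


class TestEnvelopeCurve:
    def test_b_isoform_activates_faster(self, m1, p1a, p1b):
        prot = make_envelope_protocol()
        curves = {}
        for iso, params in (("a", p1a), ("b", p1b)):
            traces = simulate_sweeps(m1, params, prot, sample_dt=0.5)
            curves[iso] = activation_envelope_curve(traces)
        d_a = np.interp(0.9, curves["a"][1], curves["a"][0])
        d_b = np.interp(0.9, curves["b"][1], curves["b"][0])
        assert d_b < d_a

    def test_single_sweep_normalizes_to_one(self, m1, p1a):
        prot = make_envelope_protocol([100.0])
        traces = simulate_sweeps(m1, p1a, prot, sample_dt=0.5)
        durations, curve = activation_envelope_curve(traces)
        assert curve.tolist() == [1.0]

    def test_invariant_under_uniform_current_scaling(self, m1, p1a):
        prot = make_envelope_protocol([5.0, 50.0, 500.0])
        traces = simulate_sweeps(m1, p1a, prot, sample_dt=0.5)
        _, base = activation_envelope_curve(traces)
        for tr in traces:
            tr.current = tr.current * 7.3
        _, scaled = activation_envelope_curve(traces)
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_nondecreasing_in_duration(self, m1, p1b):
        traces = simulate_sweeps(m1, p1b, make_envelope_protocol(), sample_dt=0.5)
        _, curve = activation_envelope_curve(traces)
        assert (np.diff(curve) >= -1e-12).all()


class TestRecovery:
    def test_b_recovers_faster_at_both_voltages(self, m1, p1a, p1b):
        prot = make_recovery_protocol()
        taus = {}
        for iso, params in (("a", p1a), ("b", p1b)):
            traces = simulate_sweeps(m1, params, prot, sample_dt=0.05)
            taus[iso] = [recovery_time_constant(tr) for tr in traces]
        for tau_a, tau_b in zip(taus["a"], taus["b"]):
            assert tau_b < tau_a

    def test_recovery_slower_at_less_negative_voltage(self, m1, p1a):
        traces = simulate_sweeps(m1, p1a, make_recovery_protocol(), sample_dt=0.05)
        by_v = {tr.sweep_value: recovery_time_constant(tr) for tr in traces}
        assert by_v[-100.0] < by_v[-50.0]


class TestIVRelationship:
    def test_bell_shape_for_both_isoforms(self, m1, p1a, p1b):
        prot = make_ssa_protocol()
        for params in (p1a, p1b):
            traces = simulate_sweeps(m1, params, prot, sample_dt=0.5)
            V, I = iv_relationship(traces)
            assert len(V) == prot.n_sweeps
            k = int(np.argmax(I))
            assert 0 < k < len(V) - 1  # interior maximum: rise then fall

    def test_b_has_more_negative_half_activation(self, m1, p1a, p1b, room_cp):
        prot = make_ssa_protocol()
        vh = {}
        for iso, params in (("a", p1a), ("b", p1b)):
            traces = simulate_sweeps(m1, params, prot, cp=room_cp)
            fit = boltzmann_fit(*ssa_activation_curve(traces))
            vh[iso] = fit.v_half
        assert vh["b"] < vh["a"]
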