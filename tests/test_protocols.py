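"""Protocol construction and sweep simulation."""

import numpy as np
import pytest

from hergkin import (
    ConfigurationError,
    CurrentParams,
    make_deactivation_protocol,
    make_envelope_protocol,
    make_recovery_protocol,
    make_ssa_protocol,
    peak_tail,
    simulate_sweeps,
)


class TestProtocolFactories:
    def test_ssa_default_sweep_count(self):
        assert make_ssa_protocol().n_sweeps == 15  # (40 - (-100))/10 + 1

    def test_ssa_coarse_increment(self):
        assert make_ssa_protocol(increment=20.0).n_sweeps == 8

    def test_ssa_tail_fixed_at_minus_100(self):
        prot = make_ssa_protocol()
        for v in prot.sweep_values:
            segs = prot.sweep_segments(v)
            assert segs[1] == (1000.0, -100.0)

    def test_envelope_default_grid(self):
        prot = make_envelope_protocol()
        assert prot.n_sweeps == 9
        assert prot.sweep_values[0] == 5.0
        for v in prot.sweep_values:
            assert prot.sweep_segments(v)[1][0] == 3000.0

    def test_deactivation_defaults(self):
        prot = make_deactivation_protocol()
        assert prot.sweep_values == (-120.0, -100.0, -60.0, -40.0)
        for v in prot.sweep_values:
            assert prot.sweep_segments(v)[1] == (5.0, -120.0)

    def test_deactivation_single_voltage(self):
        assert make_deactivation_protocol([-100.0]).n_sweeps == 1

    def test_recovery_matches_reported_voltages(self):
        prot = make_recovery_protocol()
        assert prot.sweep_values == (-100.0, -50.0)
        assert prot.measurement_segment == 1

    @pytest.mark.parametrize(
        "factory", [make_deactivation_protocol, make_recovery_protocol]
    )
    def test_empty_voltage_list_rejected(self, factory):
        with pytest.raises(ConfigurationError):
            factory([])

    def test_unsorted_sweep_values_rejected(self):
        from hergkin import VoltageProtocol

        with pytest.raises(ConfigurationError):
            VoltageProtocol(
                name="x", segments=((10.0, 0.0),), sweep_segment=0,
                sweep_kind="voltage", sweep_values=(0.0, -10.0),
                measurement_segment=0,
            )


class TestSimulateSweeps:
    def test_sample_count_per_sweep(self, m1, p1a):
        prot = make_ssa_protocol(increment=70.0)  # 3 sweeps, keep it light
        traces = simulate_sweeps(m1, p1a, prot, sample_dt=0.5)
        assert len(traces) == 3
        for tr in traces:
            assert tr.time.size == int(2000.0 / 0.5) + 1
            assert tr.segment_bounds[-1] == 2000.0

    def test_zero_current_at_reversal(self, m1, p1a, room_cp):
        from hergkin import VoltageProtocol

        prot = VoltageProtocol(
            name="rev", segments=((100.0, room_cp.EK),), sweep_segment=0,
            sweep_kind="duration", sweep_values=(100.0,), measurement_segment=0,
        )
        (trace,) = simulate_sweeps(m1, p1a, prot, cp=room_cp, sample_dt=0.5)
        assert np.abs(trace.current).max() == 0.0

    def test_b_isoform_currents_larger_and_tails_peak_earlier(
        self, m1, p1a, p1b, room_cp
    ):
        prot = make_ssa_protocol(step_min=-20.0, step_max=40.0, increment=20.0)
        tr_a = simulate_sweeps(m1, p1a, prot, cp=room_cp, sample_dt=0.5)
        tr_b = simulate_sweeps(m1, p1b, prot, cp=room_cp, sample_dt=0.5)
        for a, b in zip(tr_a, tr_b):
            # larger depolarization-step current for the b-isoform
            end_a = a.current[a.segment_slice(0)][-1]
            end_b = b.current[b.segment_slice(0)][-1]
            assert abs(end_b) > abs(end_a)
            # faster recovery from inactivation: earlier tail peak
            assert peak_tail(b).time_ms < peak_tail(a).time_ms

    def test_probability_conserved_throughout(self, m2, p2b):
        prot = make_recovery_protocol()
        traces = simulate_sweeps(m2, p2b, prot, sample_dt=0.5, keep_occupancy=True)
        for tr in traces:
            assert np.abs(tr.occupancy.sum(axis=1) - 1.0).max() < 1e-9


class TestPeakTail:
    def test_monotone_decay_peaks_at_first_sample(self, m1, p1a):
        # the 5-ms interpulse at -120 mV recovers nearly all a-isoform
        # channels, so the test-segment tail decays monotonically
        prot = make_deactivation_protocol([-100.0], test_ms=1000.0)
        (tr,) = simulate_sweeps(m1, p1a, prot, sample_dt=0.5)
        pk = peak_tail(tr, 2)
        assert pk.current < 0  # inward below EK
        assert pk.time_ms <= 0.5  # first sample of the segment

    def test_all_zero_trace_returns_zero_at_first_sample(self, m1, p1a, room_cp):
        from hergkin import VoltageProtocol

        prot = VoltageProtocol(
            name="rev", segments=((50.0, room_cp.EK),), sweep_segment=0,
            sweep_kind="duration", sweep_values=(50.0,), measurement_segment=0,
        )
        (tr,) = simulate_sweeps(m1, p1a, prot, cp=room_cp, sample_dt=0.5)
        pk = peak_tail(tr, 0, polarity=1)
        assert pk.current == 0.0 and pk.time_ms == 0.0

    def test_interior_peak_matches_dense_grid_argmax(self, m1, p1a):
        # no interpulse here: the recovery hook puts the tail peak inside
        # the segment
        prot = make_recovery_protocol([-100.0], test_ms=200.0)
        (coarse,) = simulate_sweeps(m1, p1a, prot, sample_dt=0.5)
        (dense,) = simulate_sweeps(m1, p1a, prot, sample_dt=0.05)
        pk_c, pk_d = peak_tail(coarse, 1), peak_tail(dense, 1)
        assert pk_d.time_ms > 1.0  # hooked tail: interior peak
        assert pk_c.time_ms == pytest.approx(pk_d.time_ms, abs=0.5)
        assert pk_c.current == pytest.approx(pk_d.current, rel=1e-3)
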