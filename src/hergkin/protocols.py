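"""Voltage-clamp protocols and their simulation.

A protocol is an ordered list of constant-voltage segments with one
swept quantity (a segment's voltage or duration).  Four standard
designs are provided:

* steady-state activation (SSA): 1-s depolarizing steps followed by a
  1-s tail at -100 mV; the normalized peak tails give the activation
  curve and its Boltzmann V1/2.
* envelope of tails: a +40 mV step of varying duration followed by a
  3-s tail at -100 mV; normalized peak tails trace activation onset.
* deactivation: full activation at +40 mV, a 5-ms step to -120 mV to
  recover channels from inactivation, then a long test step where the
  decaying tail is fit with exponentials.
* recovery from inactivation: full activation/inactivation at +40 mV
  then a hyperpolarized test step whose rising ("hooked") phase gives
  the recovery time constant.

Each sweep starts from the steady state at the holding potential
(-80 mV) and is propagated exactly (matrix exponential) segment by
segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .current import CurrentParams, ikr_current
from .errors import ConfigurationError, ValidationError
from .propagate import propagate_segment, steady_state
from .scheme import MarkovScheme, ParameterSet, build_generator, constrain_reversibility
from .traces import CurrentTrace

DEFAULT_SAMPLE_DT = 0.1  # ms; measurement sampling only, propagation is exact
DEFAULT_HOLDING_MV = -80.0


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered constant-voltage segments with one swept quantity.

    ``segments`` is the template (duration_ms, voltage_mV) list; the
    segment at ``sweep_segment`` has its voltage (``sweep_kind`` =
    'voltage') or duration ('duration') replaced by each entry of
    ``sweep_values`` in turn.  ``measurement_segment`` marks the segment
    analyzed downstream.
    """

    name: str
    segments: tuple[tuple[float, float], ...]
    sweep_segment: int
    sweep_kind: str
    sweep_values: tuple[float, ...]
    measurement_segment: int
    holding_potential: float = DEFAULT_HOLDING_MV

    def __post_init__(self) -> None:
        if self.sweep_kind not in ("voltage", "duration"):
            raise ConfigurationError(f"unknown sweep kind {self.sweep_kind!r}")
        if not self.sweep_values:
            raise ConfigurationError("sweep_values must be non-empty")
        if list(self.sweep_values) != sorted(self.sweep_values):
            raise ConfigurationError("sweep_values must be sorted")
        for d, _ in self.segments:
            if d <= 0:
                raise ConfigurationError("segment durations must be positive")
        if self.sweep_kind == "duration" and any(v <= 0 for v in self.sweep_values):
            raise ConfigurationError("swept durations must be positive")
        for idx in (self.sweep_segment, self.measurement_segment):
            if not 0 <= idx < len(self.segments):
                raise ConfigurationError(f"segment index {idx} out of range")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_values)

    def sweep_segments(self, value: float) -> list[tuple[float, float]]:
        """Concrete (duration, voltage) list for one sweep value."""
        segs = list(self.segments)
        d, v = segs[self.sweep_segment]
        if self.sweep_kind == "voltage":
            segs[self.sweep_segment] = (d, value)
        else:
            segs[self.sweep_segment] = (value, v)
        return segs

    def with_sweep_values(self, values) -> "VoltageProtocol":
        return replace(self, sweep_values=tuple(values))


def make_ssa_protocol(
    step_min: float = -100.0,
    step_max: float = 40.0,
    increment: float = 10.0,
    step_ms: float = 1000.0,
    tail_mv: float = -100.0,
    tail_ms: float = 1000.0,
) -> VoltageProtocol:
    """Steady-state activation: swept test step then fixed tail."""
    if step_min >= step_max:
        raise ConfigurationError("step_min must be below step_max")
    if increment <= 0:
        raise ConfigurationError("increment must be positive")
    n = int(np.floor((step_max - step_min) / increment + 1e-9)) + 1
    values = tuple(step_min + increment * i for i in range(n))
    return VoltageProtocol(
        name="ssa",
        segments=((step_ms, 0.0), (tail_ms, tail_mv)),
        sweep_segment=0,
        sweep_kind="voltage",
        sweep_values=values,
        measurement_segment=1,
    )


DEFAULT_ENVELOPE_DURATIONS = (5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)


def make_envelope_protocol(
    durations=DEFAULT_ENVELOPE_DURATIONS,
    activation_mv: float = 40.0,
    tail_mv: float = -100.0,
    tail_ms: float = 3000.0,
) -> VoltageProtocol:
    """Envelope of tails: activation step of swept duration, 3-s tail."""
    durations = tuple(float(d) for d in durations)
    if not durations:
        raise ConfigurationError("durations must be non-empty")
    return VoltageProtocol(
        name="envelope",
        segments=((durations[0], activation_mv), (tail_ms, tail_mv)),
        sweep_segment=0,
        sweep_kind="duration",
        sweep_values=durations,
        measurement_segment=1,
    )


def make_deactivation_protocol(
    test_voltages=(-120.0, -100.0, -60.0, -40.0),
    activation_ms: float = 1000.0,
    interpulse_mv: float = -120.0,
    interpulse_ms: float = 5.0,
    test_ms: float = 5000.0,
) -> VoltageProtocol:
    """Deactivation: +40 mV activation, 5-ms step to -120 mV, long test step."""
    voltages = tuple(sorted(float(v) for v in test_voltages))
    if not voltages:
        raise ConfigurationError("test_voltages must be non-empty")
    if any(not -140.0 <= v <= 0.0 for v in voltages):
        raise ConfigurationError("deactivation test voltages must lie in [-140, 0] mV")
    return VoltageProtocol(
        name="deactivation",
        segments=((activation_ms, 40.0), (interpulse_ms, interpulse_mv), (test_ms, 0.0)),
        sweep_segment=2,
        sweep_kind="voltage",
        sweep_values=voltages,
        measurement_segment=2,
    )


def make_recovery_protocol(
    test_voltages=(-100.0, -50.0),
    conditioning_ms: float = 1000.0,
    test_ms: float = 200.0,
) -> VoltageProtocol:
    """Recovery from inactivation: +40 mV conditioning then hyperpolarized test.

    The analyzed window is the rising (hooked) phase of the test-segment
    current, from segment onset to the current peak.
    """
    voltages = tuple(sorted(float(v) for v in test_voltages))
    if not voltages:
        raise ConfigurationError("test_voltages must be non-empty")
    if any(v >= 40.0 for v in voltages):
        raise ConfigurationError("test voltages must be hyperpolarized relative to +40 mV")
    return VoltageProtocol(
        name="recovery",
        segments=((conditioning_ms, 40.0), (test_ms, 0.0)),
        sweep_segment=1,
        sweep_kind="voltage",
        sweep_values=voltages,
        measurement_segment=1,
    )


BUILTIN_PROTOCOLS = {
    "ssa": make_ssa_protocol,
    "envelope": make_envelope_protocol,
    "deactivation": make_deactivation_protocol,
    "recovery": make_recovery_protocol,
}


def simulate_sweeps(
    scheme: MarkovScheme,
    params: ParameterSet,
    protocol: VoltageProtocol,
    cp: CurrentParams | None = None,
    sample_dt: float = DEFAULT_SAMPLE_DT,
    keep_occupancy: bool = False,
) -> list[CurrentTrace]:
    """Simulate every sweep of a protocol, returning one trace each.

    Each sweep is initialized at the steady state of the holding
    potential, then propagated exactly across the sweep's segments;
    the current at each sample is gKr * pO * (V - EK) with the
    segment's command voltage.
    """
    if cp is None:
        cp = CurrentParams()
    params = constrain_reversibility(scheme, params)
    params.validate_against(scheme)
    p_hold = steady_state(build_generator(scheme, params, protocol.holding_potential))
    open_idx = scheme.open_index
    traces = []
    for value in protocol.sweep_values:
        segs = protocol.sweep_segments(value)
        chunks_t, chunks_p = [], []
        bounds = [0.0]
        t0 = 0.0
        p = p_hold
        for duration, V in segs:
            Q = build_generator(scheme, params, V)
            P = propagate_segment(p, Q, duration, sample_dt)
            n = P.shape[0]
            t = t0 + np.arange(n) * sample_dt
            if chunks_t:
                # drop the duplicate boundary sample
                t, P = t[1:], P[1:]
            chunks_t.append(t)
            chunks_p.append(P)
            p = P[-1]
            t0 += duration
            bounds.append(t0)
        time = np.concatenate(chunks_t)
        occ = np.concatenate(chunks_p, axis=0)
        pO = occ[:, open_idx]
        current = np.empty_like(pO)
        seg_starts = np.array(bounds[:-1])
        for k, (duration, V) in enumerate(segs):
            # the sample at a voltage-step boundary belongs to the
            # preceding segment: segments own (t0, t1], the first owns [0, t1]
            eps = -1e-9 if k == 0 else 1e-9
            lo = int(np.searchsorted(time, seg_starts[k] + eps))
            hi = int(np.searchsorted(time, bounds[k + 1] + 1e-9))
            current[lo:hi] = ikr_current(pO[lo:hi], V, cp)
        traces.append(
            CurrentTrace(
                time=time,
                current=current,
                segment_bounds=np.array(bounds),
                segment_voltages=np.array([v for _, v in segs]),
                sweep_value=float(value),
                conditions={
                    "protocol": protocol.name,
                    "scheme": scheme.name,
                    "isoform": params.isoform,
                    "T_K": cp.T,
                    "Ko_mM": cp.Ko,
                    "EK_mV": cp.EK,
                    "sample_dt_ms": sample_dt,
                },
                open_prob=pO,
                occupancy=occ if keep_occupancy else None,
            )
        )
    return traces
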