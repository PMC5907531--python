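"""Derived measurements: tail peaks, Boltzmann and exponential fits.

These are the quantities the voltage protocols exist to produce:
normalized activation curves and their half-activation voltage,
deactivation time constants from double-exponential fits of tail
currents, recovery time constants from the rising phase of hooked
tails, envelope-of-tails activation curves, and the I-V relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .rates import evaluate_rate
from .scheme import ParameterSet
from .traces import CurrentTrace


@dataclass(frozen=True)
class PeakMeasurement:
    """Signed extremum of a trace segment and its time from segment start."""

    current: float
    time_ms: float


def peak_tail(
    trace: CurrentTrace, segment_index: int | None = None, polarity: int | None = None
) -> PeakMeasurement:
    """Signed peak current within a segment.

    ``polarity`` (+1 outward / -1 inward) selects which extremum counts
    as the peak; when omitted it is inferred from the sign of
    (V_segment - EK), i.e. tails below the reversal potential are
    inward.  The returned time is relative to segment start.
    """
    if segment_index is None:
        segment_index = trace.n_segments - 1
    sl = trace.segment_slice(segment_index)
    y = trace.current[sl]
    if y.size == 0:
        raise ValidationError("empty segment window")
    if polarity is None:
        V = trace.segment_voltages[segment_index]
        EK = trace.conditions.get("EK_mV")
        if EK is None:
            raise ValidationError("polarity not given and EK_mV missing from conditions")
        polarity = 1 if V >= EK else -1
    idx = int(np.argmax(polarity * y))
    t = trace.segment_time(segment_index)
    return PeakMeasurement(current=float(y[idx]), time_ms=float(t[idx]))


@dataclass(frozen=True)
class BoltzmannFit:
    """Single Boltzmann I/Imax = 1 / (1 + exp((V1/2 - V) / k))."""

    v_half: float
    slope: float
    residual_norm: float

    def __call__(self, V):
        return 1.0 / (1.0 + np.exp((self.v_half - np.asarray(V)) / self.slope))


def boltzmann_fit(V, I_norm) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a normalized activation curve.

    Requires at least 4 points spanning the transition; the fitted
    curve equals 0.5 at V1/2 by construction.
    """
    V = np.asarray(V, dtype=float)
    y = np.asarray(I_norm, dtype=float)
    if V.size != y.size or V.size < 4:
        raise ValidationError("need >= 4 (V, I) points for a Boltzmann fit")

    def model(v, vh, k):
        return 1.0 / (1.0 + np.exp((vh - v) / k))

    # seed V1/2 at the half-maximum crossing, slope from the 0.25-0.75 span
    order = np.argsort(V)
    vh0 = float(np.interp(0.5, y[order], V[order]))
    k0 = max((V.max() - V.min()) / 10.0, 1.0)
    try:
        popt, _ = curve_fit(model, V, y, p0=[vh0, k0], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from None
    vh, k = float(popt[0]), float(popt[1])
    if k <= 0:
        raise FitError(f"Boltzmann fit produced non-positive slope k = {k}")
    resid = float(np.linalg.norm(model(V, vh, k) - y))
    return BoltzmannFit(v_half=vh, slope=k, residual_norm=resid)


@dataclass(frozen=True)
class ExpFit:
    """Sum of exponentials y(t) = sum_i A_i exp(-t/tau_i) + C.

    Components are ordered fastest first (tau ascending).
    """

    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    offset: float
    residual_norm: float

    @property
    def n_components(self) -> int:
        return len(self.taus)

    @property
    def tau_fast(self) -> float:
        return self.taus[0]

    @property
    def tau_slow(self) -> float:
        return self.taus[-1]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for A, tau in zip(self.amplitudes, self.taus):
            y = y + A * np.exp(-t / tau)
        return y


def _tau_seeds(t: np.ndarray, y: np.ndarray, n: int) -> list[float]:
    """Log-linear probe of the decay for initial time constants."""
    span = t[-1] - t[0]
    amp = y - y[-1]
    sign = 1.0 if abs(amp.max()) >= abs(amp.min()) else -1.0
    z = sign * amp
    mask = z > max(z.max(), 1e-300) * 1e-3
    if mask.sum() >= 3:
        coeffs = np.polyfit(t[mask], np.log(z[mask]), 1)
        tau = -1.0 / coeffs[0] if coeffs[0] < 0 else span / 3.0
    else:
        tau = span / 3.0
    tau = float(np.clip(tau, 1e-3, 10 * span))
    if n == 1:
        return [tau]
    return [tau / 5.0, tau * 2.0]


def exp_fit(
    trace_or_t,
    y=None,
    n_components: int = 2,
    window: tuple[float, float] | None = None,
    segment_index: int | None = None,
    tau_min: float = 0.0,
) -> ExpFit:
    """Fit a mono- or double-exponential decay.

    Accepts either ``(t, y)`` arrays or a :class:`CurrentTrace` with an
    optional ``segment_index`` and a ``window`` (ms, relative to segment
    start) restricting the fitted samples.  Time constants are
    constrained positive and reported fastest first; amplitudes are
    unconstrained in sign, which also covers hooked (rise-then-decay)
    windows.  ``tau_min`` floors the admissible time constants - used to
    keep a fit from latching onto a known faster process (e.g. the
    O <-> I exchange transient superimposed on a deactivating tail).
    """
    if isinstance(trace_or_t, CurrentTrace):
        trace = trace_or_t
        if segment_index is None:
            segment_index = trace.n_segments - 1
        sl = trace.segment_slice(segment_index)
        t = trace.segment_time(segment_index)
        y = trace.current[sl]
    else:
        t = np.asarray(trace_or_t, dtype=float)
        y = np.asarray(y, dtype=float)
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if t.size < 3 * n_components + 1:
        raise FitError("degenerate window: too few samples for exponential fit")
    t = t - t[0]
    scale = np.abs(y).max()
    if scale == 0:
        raise FitError("degenerate window: all-zero signal")

    tau_g = max(_tau_seeds(t, y, 1)[0], tau_min * 1.5 + 1e-9)
    span = t[-1] if t[-1] > 0 else 1.0
    a0 = y[0] - y[-1]
    big = np.inf
    if n_components == 1:
        def model(tt, A, tau, C):
            return A * np.exp(-tt / tau) + C

        try:
            popt, _ = curve_fit(
                model, t, y, p0=[a0, tau_g, y[-1]],
                bounds=([-big, tau_min, -big], [big, big, big]),
                maxfev=40000, method="trf",
            )
        except RuntimeError as exc:
            raise FitError(f"exponential fit did not converge: {exc}") from None
        resid = float(np.linalg.norm(model(t, *popt) - y))
    else:
        def model(tt, A1, t1, A2, t2, C):
            return A1 * np.exp(-tt / t1) + A2 * np.exp(-tt / t2) + C

        lo = [-big, tau_min, -big, tau_min, -big]
        hi = [big, big, big, big, big]
        floor = max(tau_min, 1e-3)
        # two-exponential fits of near-degenerate decays depend strongly
        # on the seed; probe several tau splittings and keep the best
        # non-degenerate solution (distinct taus, non-vanishing amplitudes)
        seed_pairs = [
            (tau_g / 5.0, tau_g * 2.0),
            (tau_g / 15.0, tau_g),
            (2.0 * floor, span / 4.0),
            (span / 30.0, span / 3.0),
        ]
        best = None          # (resid, popt), degeneracy-screened
        best_any = None      # unconditional fallback
        for t1s, t2s in seed_pairs:
            t1s = max(t1s, floor * 1.05)
            t2s = max(t2s, t1s * 2.0)
            try:
                popt_i, _ = curve_fit(
                    model, t, y,
                    p0=[a0 * 0.5, t1s, a0 * 0.5, t2s, y[-1]],
                    bounds=(lo, hi), maxfev=40000, method="trf",
                )
            except RuntimeError:
                continue
            r = float(np.linalg.norm(model(t, *popt_i) - y))
            if best_any is None or r < best_any[0]:
                best_any = (r, popt_i)
            tt1, tt2 = sorted((popt_i[1], popt_i[3]))
            amp_tot = abs(popt_i[0]) + abs(popt_i[2])
            ok = (
                tt2 >= 1.5 * tt1
                and amp_tot > 0
                and min(abs(popt_i[0]), abs(popt_i[2])) >= 0.01 * amp_tot
            )
            if ok and (best is None or r < best[0]):
                best = (r, popt_i)
        if best is None:
            best = best_any
        if best is None:
            raise FitError("exponential fit did not converge from any seed")
        resid, popt = best
    if n_components == 1:
        amps, taus, offset = (float(popt[0]),), (abs(float(popt[1])),), float(popt[2])
    else:
        pairs = sorted(
            [(abs(float(popt[1])), float(popt[0])), (abs(float(popt[3])), float(popt[2]))]
        )
        taus = tuple(p[0] for p in pairs)
        amps = tuple(p[1] for p in pairs)
        offset = float(popt[4])
    if any(tau <= 0 for tau in taus):
        raise FitError("exponential fit produced non-positive time constant")
    return ExpFit(amplitudes=amps, taus=taus, offset=offset, residual_norm=resid)


def ssa_activation_curve(
    traces: list[CurrentTrace], segment_index: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(step voltage, normalized peak tail magnitude) from SSA sweeps.

    The activation curve fit by :func:`boltzmann_fit`: peak tail
    currents normalized to the largest magnitude, values in [0, 1].
    """
    V = np.array([tr.sweep_value for tr in traces])
    peaks = np.array([peak_tail(tr, segment_index).current for tr in traces])
    top = np.abs(peaks).max()
    if top == 0:
        raise ValidationError("all SSA peak tails are zero; cannot normalize")
    order = np.argsort(V)
    return V[order], (np.abs(peaks) / top)[order]


def activation_envelope_curve(traces: list[CurrentTrace]) -> tuple[np.ndarray, np.ndarray]:
    """(activation duration, normalized peak tail) from envelope sweeps.

    Peaks are normalized to the largest magnitude; values lie in [0, 1]
    and the maximum is exactly 1.  Invariant under uniform scaling of
    all currents.
    """
    if len(traces) < 1:
        raise ValidationError("need at least one envelope sweep")
    durations = np.array([tr.sweep_value for tr in traces])
    peaks = np.array([peak_tail(tr).current for tr in traces])
    top = np.abs(peaks).max()
    if top == 0:
        raise ValidationError("all envelope peaks are zero; cannot normalize")
    order = np.argsort(durations)
    return durations[order], (np.abs(peaks) / top)[order]


def iv_relationship(
    traces: list[CurrentTrace], segment_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(step voltage, end-of-step current) per sweep of an SSA-style run."""
    V = np.array([tr.sweep_value for tr in traces])
    I = np.array(
        [tr.current[tr.segment_slice(segment_index)][-1] for tr in traces]
    )
    order = np.argsort(V)
    return V[order], I[order]


def deactivation_mode_taus(scheme, params, V: float, n: int = 2) -> tuple[float, ...]:
    """The model's n slowest relaxation time constants at voltage V.

    The eigenvalues of the generator give the exact exponential
    components of any relaxation at fixed voltage; the slowest nonzero
    modes are the deactivation components of a tail current, free of
    the amplitude and windowing sensitivities of a finite-window
    double-exponential fit (the fitted route remains the estimator for
    measured time courses).  Returned fastest first, like
    :class:`ExpFit`.
    """
    from .scheme import build_generator, constrain_reversibility

    params = constrain_reversibility(scheme, params)
    Q = build_generator(scheme, params, V)
    w = np.sort(np.real(np.linalg.eigvals(Q)))  # ascending: most negative first
    taus = sorted(-1.0 / x for x in w if x < -1e-12)
    if len(taus) < n:
        raise ValidationError(f"generator has fewer than {n} decaying modes")
    return tuple(taus[-n:])


def inactivation_exchange_time(params: ParameterSet, V: float) -> float:
    """Relaxation time (ms) of the O <-> I exchange at voltage V.

    1 / (k_OI + k_IO); the timescale of the hooked-tail transient that
    precedes true deactivation in a tail current.
    """
    k_oi = evaluate_rate(params.rate("bi"), V)
    k_io = evaluate_rate(params.rate("ai"), V)
    return 1.0 / (k_oi + k_io)


def deactivation_time_constants(
    trace: CurrentTrace,
    skip_ms: float = 0.0,
    n_components: int = 2,
    tau_min: float = 0.0,
) -> ExpFit:
    """Double-exponential fit of a deactivating tail current.

    The fit window starts at the post-hook current peak plus
    ``skip_ms``; ``tau_min`` floors the fitted time constants.  Both
    guards exist for the same reason: the rising phase and the O <-> I
    re-equilibration transient are not part of the deactivation decay
    and would otherwise contaminate the fast component.  When the
    generating model is known, pass a few
    :func:`inactivation_exchange_time` at the test voltage for both.
    """
    seg = trace.n_segments - 1
    sl = trace.segment_slice(seg)
    t = trace.segment_time(seg)
    y = trace.current[sl]
    polarity = 1 if y[np.argmax(np.abs(y))] >= 0 else -1
    ipk = int(np.argmax(polarity * y))
    start = t[ipk] + skip_ms
    return exp_fit(
        t, y, n_components=n_components, window=(start, t[-1]), tau_min=tau_min
    )


def recovery_time_constant(trace: CurrentTrace) -> float:
    """Recovery-from-inactivation tau from the rising phase of a hooked tail.

    Fits A * (1 - exp(-t/tau)) to |I| from test-segment onset to the
    current peak.
    """
    seg = trace.n_segments - 1
    sl = trace.segment_slice(seg)
    t = trace.segment_time(seg)
    y = np.abs(trace.current[sl])
    ipk = int(np.argmax(y))
    if ipk < 3:
        raise FitError("no rising phase detected in recovery window")
    tt, yy = t[: ipk + 1], y[: ipk + 1]

    def model(x, A, tau):
        return A * (1.0 - np.exp(-x / np.abs(tau)))

    try:
        popt, _ = curve_fit(model, tt, yy, p0=[yy[-1], max(tt[-1] / 3.0, 0.1)], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}") from None
    return abs(float(popt[1]))
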