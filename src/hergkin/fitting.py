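"""Weighted multi-protocol global fitting of correction factors.

The base rate parameters (alpha, beta) stay frozen at their reference
values; what is optimized are the dimensionless corrections (a, b) on a
chosen subset of transitions, so k(V) = a*alpha*exp(b*beta*V).  The
cost is a weighted sum over datasets of squared differences between
simulated and target observables, where the observables are the derived
curves the protocols are designed to measure (normalized peak-tail
activation points, envelope curves, deactivation time courses, recovery
time constants) rather than raw traces.

``global_fit`` runs a bounded trust-region least-squares from multiple
seeded starting points (the identity correction plus log-uniform
perturbations) and keeps the best; reruns with the same seed are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .current import CurrentParams
from .errors import ConfigurationError, FitError
from .measure import recovery_time_constant
from .protocols import VoltageProtocol, simulate_sweeps
from .scheme import MarkovScheme, ParameterSet
from .traces import CurrentTrace

logger = logging.getLogger(__name__)

OBSERVABLE_KINDS = ("ssa", "envelope", "deactivation", "recovery_tau")

DEFAULT_BOUNDS_A = (0.01, 100.0)
DEFAULT_BOUNDS_B = (0.2, 5.0)

_PENALTY = 1e6
_DEACT_SUBSAMPLE_MS = 10.0


def simulate_observable(
    scheme: MarkovScheme,
    params: ParameterSet,
    protocol: VoltageProtocol,
    kind: str,
    cp: CurrentParams | None = None,
    sample_dt: float = 0.5,
) -> np.ndarray:
    """Simulate a protocol and reduce it to the fitted observable vector.

    * ``ssa``: signed peak tail per sweep, normalized by the largest
      magnitude (the points of the activation curve).
    * ``envelope``: peak tail magnitude per sweep normalized to max.
    * ``deactivation``: per-sweep tail time course in the measurement
      segment, peak-normalized and subsampled every 10 ms, concatenated
      across sweeps.
    * ``recovery_tau``: rising-phase recovery time constant per sweep.
    """
    from .measure import activation_envelope_curve, peak_tail  # cycle-free import

    if kind not in OBSERVABLE_KINDS:
        raise ConfigurationError(f"unknown observable kind {kind!r}")
    traces = simulate_sweeps(scheme, params, protocol, cp=cp, sample_dt=sample_dt)
    if kind == "ssa":
        peaks = np.array(
            [peak_tail(tr, protocol.measurement_segment).current for tr in traces]
        )
        return peaks / np.abs(peaks).max()
    if kind == "envelope":
        _, curve = activation_envelope_curve(traces)
        return curve
    if kind == "deactivation":
        return np.concatenate([_deactivation_course(tr) for tr in traces])
    taus = np.array([recovery_time_constant(tr) for tr in traces])
    return taus


def _deactivation_course(trace: CurrentTrace) -> np.ndarray:
    """Peak-normalized measurement-segment time course on a 10-ms grid."""
    seg = trace.n_segments - 1
    sl = trace.segment_slice(seg)
    t = trace.segment_time(seg)
    y = trace.current[sl]
    peak = np.abs(y).max()
    if peak == 0:
        return np.zeros(int(t[-1] // _DEACT_SUBSAMPLE_MS) + 1)
    grid = np.arange(0.0, t[-1] + 1e-9, _DEACT_SUBSAMPLE_MS)
    return np.interp(grid, t, y / peak)


@dataclass
class Dataset:
    """One protocol's target observable with its partial-cost weight."""

    protocol: VoltageProtocol
    kind: str
    targets: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in OBSERVABLE_KINDS:
            raise ConfigurationError(f"unknown observable kind {self.kind!r}")
        if self.weight <= 0:
            raise ConfigurationError("dataset weight must be positive")
        self.targets = np.asarray(self.targets, dtype=float)


@dataclass
class FitProblem:
    """Datasets, free corrections, and bounds for a global fit.

    ``free`` lists (transition name, 'a'|'b') pairs naming which
    correction factors are optimized; everything else stays at its
    value in ``base_params``.  corr_a is optimized in log space
    (positivity by construction), corr_b in linear space.
    """

    scheme: MarkovScheme
    base_params: ParameterSet
    datasets: list[Dataset]
    free: list[tuple[str, str]]
    bounds_a: tuple[float, float] = DEFAULT_BOUNDS_A
    bounds_b: tuple[float, float] = DEFAULT_BOUNDS_B
    cp: CurrentParams = field(default_factory=CurrentParams)
    sample_dt: float = 0.5

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ConfigurationError("need at least one dataset")
        if not self.free:
            raise ConfigurationError("need at least one free correction")
        for lo, hi, label in (
            (*self.bounds_a, "corr_a"), (*self.bounds_b, "corr_b"),
        ):
            if not lo < 1.0 < hi:
                raise ConfigurationError(
                    f"{label} bounds ({lo}, {hi}) must contain the identity 1"
                )
        names = {t.name for t in self.scheme.free_transitions()}
        for name, which in self.free:
            if name not in names:
                raise ConfigurationError(f"free correction on unknown transition {name!r}")
            if which not in ("a", "b"):
                raise ConfigurationError("correction selector must be 'a' or 'b'")

    # -- parameter vector encoding ------------------------------------
    def pack(self, corrections: dict[str, tuple[float, float]]) -> np.ndarray:
        x = []
        for name, which in self.free:
            ca, cb = corrections.get(name, (1.0, 1.0))
            x.append(np.log(ca) if which == "a" else cb)
        return np.array(x)

    def unpack(self, x: np.ndarray) -> dict[str, tuple[float, float]]:
        corr: dict[str, list[float]] = {}
        for (name, which), val in zip(self.free, x):
            pair = corr.setdefault(name, [1.0, 1.0])
            if which == "a":
                pair[0] = float(np.exp(val))
            else:
                pair[1] = float(val)
        return {k: (v[0], v[1]) for k, v in corr.items()}

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for _, which in self.free:
            if which == "a":
                lo.append(np.log(self.bounds_a[0]))
                hi.append(np.log(self.bounds_a[1]))
            else:
                lo.append(self.bounds_b[0])
                hi.append(self.bounds_b[1])
        return np.array(lo), np.array(hi)

    def params_for(self, x: np.ndarray) -> ParameterSet:
        return self.base_params.with_corrections(self.unpack(x))


def _residual_vector(x: np.ndarray, problem: FitProblem) -> np.ndarray:
    """Weighted residuals; simulation failure yields a large flat penalty."""
    params = problem.params_for(x)
    chunks = []
    for ds in problem.datasets:
        try:
            sim = simulate_observable(
                problem.scheme, params, ds.protocol, ds.kind,
                cp=problem.cp, sample_dt=problem.sample_dt,
            )
            r = (sim - ds.targets) * np.sqrt(ds.weight)
        except Exception as exc:  # noqa: BLE001 - any failure becomes a penalty
            logger.warning("simulation failed at x=%s (%s); penalizing", x, exc)
            r = np.full(ds.targets.size, np.sqrt(_PENALTY * ds.weight / ds.targets.size))
        chunks.append(np.atleast_1d(r))
    return np.concatenate(chunks)


def residual_cost(corrections: dict[str, tuple[float, float]], problem: FitProblem) -> float:
    """Weighted sum of squared residuals at the given corrections."""
    x = problem.pack(corrections)
    r = _residual_vector(x, problem)
    return float(r @ r)


@dataclass
class FitResult:
    """Outcome of a multi-start global fit."""

    corrections: dict[str, tuple[float, float]]
    params: ParameterSet
    cost: float
    per_dataset_cost: list[float]
    start_costs: list[float]
    best_start: int
    n_starts: int
    seed: int | None
    success: bool
    message: str

    @property
    def effective_rates(self) -> dict[str, tuple[float, float]]:
        """(effective alpha, effective beta) per transition after corrections."""
        return {
            name: (law.effective_alpha, law.effective_beta)
            for name, law in self.params.rates.items()
        }


def _per_dataset_costs(x: np.ndarray, problem: FitProblem) -> list[float]:
    params = problem.params_for(x)
    out = []
    for ds in problem.datasets:
        sim = simulate_observable(
            problem.scheme, params, ds.protocol, ds.kind,
            cp=problem.cp, sample_dt=problem.sample_dt,
        )
        out.append(float(ds.weight * np.sum((sim - ds.targets) ** 2)))
    return out


def global_fit(
    problem: FitProblem,
    n_starts: int = 10,
    seed: int | None = 0,
    optimizer_options: dict | None = None,
) -> FitResult:
    """Multi-start bounded least-squares over the correction factors.

    Start 0 is the identity correction; the remaining starts perturb it
    log-uniformly (corr_a) / uniformly (corr_b) within bounds using a
    generator seeded by ``seed``, so identical seeds reproduce the
    identical sequence of starts and hence the identical result.
    """
    if n_starts < 1:
        raise ConfigurationError("n_starts must be >= 1")
    opts = {"xtol": 1e-10, "ftol": 1e-10, "gtol": 1e-10}
    if optimizer_options:
        opts.update(optimizer_options)
    lo, hi = problem.vector_bounds()
    rng = np.random.default_rng(seed)
    starts = [problem.pack({})]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(lo, hi))

    best = None
    start_costs: list[float] = []
    failures: list[str] = []
    for i, x0 in enumerate(starts):
        try:
            res = least_squares(
                _residual_vector, x0, bounds=(lo, hi), args=(problem,), **opts
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(f"start {i}: {exc}")
            start_costs.append(float("inf"))
            continue
        cost = float(res.fun @ res.fun)
        start_costs.append(cost)
        logger.info("start %d: cost %.6g", i, cost)
        if best is None or cost < best[1]:
            best = (i, cost, res)
    if best is None:
        raise FitError("all fit starts failed: " + "; ".join(failures))
    i_best, cost, res = best
    return FitResult(
        corrections=problem.unpack(res.x),
        params=problem.params_for(res.x),
        cost=cost,
        per_dataset_cost=_per_dataset_costs(res.x, problem),
        start_costs=start_costs,
        best_start=i_best,
        n_starts=n_starts,
        seed=seed,
        success=bool(res.success),
        message=str(res.message),
    )


@dataclass(frozen=True)
class StabilityEntry:
    parameter: tuple[str, str]
    cost_plus: float
    cost_minus: float
    curvature: float
    unidentifiable: bool


def stability_check(
    result: FitResult,
    problem: FitProblem,
    epsilon: float = 0.01,
    floor: float = 1e-6,
) -> list[StabilityEntry]:
    """Probe cost curvature around the optimum, flagging flat directions.

    Each free parameter is perturbed by +/- ``epsilon`` (relative, in
    its optimization space) and the cost recomputed; a parameter whose
    perturbation changes the cost by less than ``floor`` on both sides
    is flagged unidentifiable.
    """
    x_opt = problem.pack(result.corrections)
    r0 = _residual_vector(x_opt, problem)
    c0 = float(r0 @ r0)
    entries = []
    for j, key in enumerate(problem.free):
        step = epsilon * max(abs(x_opt[j]), 1.0)
        costs = []
        for sgn in (+1.0, -1.0):
            x = x_opt.copy()
            x[j] += sgn * step
            r = _residual_vector(x, problem)
            costs.append(float(r @ r))
        curv = (costs[0] + costs[1] - 2.0 * c0) / step**2
        flat = abs(costs[0] - c0) < floor and abs(costs[1] - c0) < floor
        entries.append(
            StabilityEntry(
                parameter=key,
                cost_plus=costs[0],
                cost_minus=costs[1],
                curvature=curv,
                unidentifiable=flat,
            )
        )
    return entries
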