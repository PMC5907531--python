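"""Single-cell action potentials with Markov I_Kr.

The gating models plug into a ventricular ionic model through a narrow
seam: anything that can report dV/dt, an updated internal state and its
named currents for a given (V, state, dt, stimulus) will do.  A minimal
surrogate ventricular model is shipped so every cell- and tissue-level
property is testable at desk scale; a full human ventricular myocyte
model can be substituted through the same interface.

The surrogate carries four currents (pA/pF, Cm = 1 uF/cm^2):

* a fast inward current ``g_fast * m_inf(V) * h * (V - 50)`` with
  instantaneous activation and a 1-ms inactivation gate - the upstroke,
  strong enough to sustain propagation at physiological tissue coupling;
* a sustained inward current ``g_ca * d_inf(V) * f * (V - 55)`` with a
  200-ms inactivation gate - the plateau;
* an inward-rectifier background ``g_k1 * r_inf(V) * (V - EK)`` that
  anchors the resting potential;
* a small plateau-range outward K current
  ``g_kp * x_inf(V) * (V - EK)`` providing repolarization reserve at
  depolarized voltages where the rectifier is shut;
* the Markov I_Kr mixture current with cell-context conductance scale
  gKr = 0.0422 and the usual sqrt(Ko/5.4) scaling.

An isoform mixture carries an independent Markov state vector per
isoform; the mixture current is the fraction-weighted sum, i.e. both
homotetramer populations see the same voltage but gate independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from . import _kernels
from .constants import BATH_K_MM, BODY_TEMPERATURE_K, PIPETTE_K_MM
from .current import nernst_potential
from .errors import NoAPError, NumericalError, ValidationError
from .propagate import steady_state
from .scheme import MarkovScheme, ParameterSet, build_generator, constrain_reversibility

CELL_GKR_SCALE = 0.0422
"""Cell-context maximal I_Kr conductance (pA/pF/mV) at 310 K, 5.4 mM Ko."""


@dataclass(frozen=True)
class IsoformMix:
    """Relative abundance of hERG1b homotetramers in the I_Kr population."""

    fraction_b: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_b <= 1.0:
            raise ValidationError("fraction_b must lie in [0, 1]")


def cell_gkr(T: float = BODY_TEMPERATURE_K, Ko: float = BATH_K_MM) -> float:
    """Cell-context gKr with the linear temperature and sqrt-Ko scalings."""
    factor = T / 35.0 - 55.0 / 7.0
    if factor <= 0:
        raise ValidationError(f"temperature factor non-positive at T={T} K")
    return CELL_GKR_SCALE * factor * math.sqrt(Ko / BATH_K_MM)


def advance_markov_rk4(p: np.ndarray, Q: np.ndarray, dt: float) -> np.ndarray:
    """One classical RK4 step of dp/dt = Q p at frozen voltage.

    At dt <= 0.005 ms and physiological rates this matches
    expm(Q dt) @ p to well below 1e-8 per state.
    """
    k1 = Q @ p
    k2 = Q @ (p + 0.5 * dt * k1)
    k3 = Q @ (p + 0.5 * dt * k2)
    k4 = Q @ (p + dt * k3)
    return p + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


class MarkovIKrComponent:
    """Stateful I_Kr mixture current for embedding in an ionic model.

    Keeps one Markov state vector per isoform; :meth:`step` advances
    both at frozen voltage (operator splitting) and returns the
    fraction-weighted mixture current density.
    """

    def __init__(
        self,
        scheme: MarkovScheme,
        params_a: ParameterSet,
        params_b: ParameterSet,
        mix: IsoformMix,
        T: float = BODY_TEMPERATURE_K,
        Ko: float = BATH_K_MM,
        Ki: float = PIPETTE_K_MM,
    ) -> None:
        self.scheme = scheme
        self.params_a = constrain_reversibility(scheme, params_a)
        self.params_b = constrain_reversibility(scheme, params_b)
        self.mix = mix
        self.gkr = cell_gkr(T, Ko)
        self.EK = nernst_potential(Ki, Ko, T)
        self.reset(-80.0)

    def reset(self, V: float) -> None:
        """Set both isoform states to steady state at voltage V."""
        self.p_a = steady_state(build_generator(self.scheme, self.params_a, V))
        self.p_b = steady_state(build_generator(self.scheme, self.params_b, V))

    @property
    def open_probability(self) -> float:
        i = self.scheme.open_index
        fb = self.mix.fraction_b
        return float((1 - fb) * self.p_a[i] + fb * self.p_b[i])

    def current(self, V: float) -> float:
        return self.gkr * self.open_probability * (V - self.EK)

    def step(self, V: float, dt: float) -> float:
        """Advance both isoforms' states by dt at voltage V; return I_Kr."""
        Qa = build_generator(self.scheme, self.params_a, V)
        Qb = build_generator(self.scheme, self.params_b, V)
        self.p_a = advance_markov_rk4(self.p_a, Qa, dt)
        self.p_b = advance_markov_rk4(self.p_b, Qb, dt)
        for p in (self.p_a, self.p_b):
            leak = abs(p.sum() - 1.0)
            if leak > 1e-6:
                raise NumericalError(f"Markov probability leak {leak:.2e}")
        return self.current(V)

    def step_expm(self, V: float, dt: float) -> float:
        """Reference step using the exact matrix exponential (slow)."""
        Qa = build_generator(self.scheme, self.params_a, V)
        Qb = build_generator(self.scheme, self.params_b, V)
        self.p_a = expm(Qa * dt) @ self.p_a
        self.p_b = expm(Qb * dt) @ self.p_b
        return self.current(V)


def markov_ikr_component(
    scheme: MarkovScheme,
    params_a: ParameterSet,
    params_b: ParameterSet,
    mix: IsoformMix,
    **kwargs,
) -> MarkovIKrComponent:
    """Build a stateful I_Kr mixture component (convenience wrapper)."""
    return MarkovIKrComponent(scheme, params_a, params_b, mix, **kwargs)


@dataclass
class SurrogateVentricularModel:
    """Minimal excitable ventricular cell built around the Markov I_Kr.

    Conductances are in mS/uF (equivalently pA/pF/mV).  Defaults are
    tuned to give a resting potential near -83 mV, an overshoot to
    positive voltages, a dome-shaped plateau near +20 mV and an action
    potential duration of a few hundred ms - the regime where I_Kr
    controls late repolarization.
    """

    scheme: MarkovScheme
    params_a: ParameterSet
    params_b: ParameterSet
    g_k1: float = 0.75
    g_fast: float = 6.0
    g_ca: float = 0.045
    g_kp: float = 0.004
    tau_h: float = 1.0
    tau_f: float = 200.0
    E_fast: float = 50.0
    E_plateau: float = 55.0
    T: float = BODY_TEMPERATURE_K
    Ko: float = BATH_K_MM
    Ki: float = PIPETTE_K_MM
    gkr: float = field(init=False)
    EK: float = field(init=False)

    def __post_init__(self) -> None:
        self.params_a = constrain_reversibility(self.scheme, self.params_a)
        self.params_b = constrain_reversibility(self.scheme, self.params_b)
        self.gkr = cell_gkr(self.T, self.Ko)
        self.EK = nernst_potential(self.Ki, self.Ko, self.T)

    # gate steady states -------------------------------------------------
    @staticmethod
    def m_inf(V):
        return 1.0 / (1.0 + np.exp(-(V + 40.0) / 6.0))

    @staticmethod
    def h_inf(V):
        return 1.0 / (1.0 + np.exp((V + 70.0) / 6.0))

    @staticmethod
    def d_inf(V):
        return 1.0 / (1.0 + np.exp(-(V + 15.0) / 6.0))

    @staticmethod
    def f_inf(V):
        return 1.0 / (1.0 + np.exp((V + 30.0) / 6.0))

    @staticmethod
    def r_inf(V):
        return 1.0 / (1.0 + np.exp((V + 60.0) / 10.0))

    @staticmethod
    def x_inf(V):
        return 1.0 / (1.0 + np.exp(-(V - 10.0) / 8.0))

    def _markov_steady(self, V: float) -> tuple[np.ndarray, np.ndarray]:
        pa = steady_state(build_generator(self.scheme, self.params_a, V))
        pb = steady_state(build_generator(self.scheme, self.params_b, V))
        return pa, pb

    def total_current(self, V: float, h: float, f: float, po: float) -> float:
        """Sum of membrane currents (pA/pF) at the given state."""
        i_k1 = self.g_k1 * self.r_inf(V) * (V - self.EK)
        i_fast = self.g_fast * self.m_inf(V) * h * (V - self.E_fast)
        i_pl = self.g_ca * self.d_inf(V) * f * (V - self.E_plateau)
        i_kp = self.g_kp * self.x_inf(V) * (V - self.EK)
        i_kr = self.gkr * po * (V - self.EK)
        return i_k1 + i_fast + i_pl + i_kp + i_kr

    def resting_potential(self, mix: IsoformMix) -> float:
        """Equilibrium voltage where all currents balance (gates at inf)."""
        fb = mix.fraction_b

        def net(V: float) -> float:
            pa, pb = self._markov_steady(V)
            io = self.scheme.open_index
            po = (1 - fb) * pa[io] + fb * pb[io]
            return self.total_current(V, self.h_inf(V), self.f_inf(V), po)

        return brentq(net, -95.0, -55.0, xtol=1e-12)

    def rest_state(self, mix: IsoformMix) -> dict:
        """Full resting state: equilibrium V, gates and Markov vectors."""
        V = self.resting_potential(mix)
        pa, pb = self._markov_steady(V)
        return {
            "V": V,
            "h": self.h_inf(V),
            "f": self.f_inf(V),
            "p_a": pa,
            "p_b": pb,
        }

    def step(self, V: float, state: dict, dt: float, stim: float, mix: IsoformMix):
        """One explicit step of the interface contract.

        Returns (dV/dt, updated state, named currents).  The Markov
        states advance at frozen V; HH gates relax exactly.
        """
        io = self.scheme.open_index
        Qa = build_generator(self.scheme, self.params_a, V)
        Qb = build_generator(self.scheme, self.params_b, V)
        p_a = advance_markov_rk4(state["p_a"], Qa, dt)
        p_b = advance_markov_rk4(state["p_b"], Qb, dt)
        eh = 1.0 - math.exp(-dt / self.tau_h)
        ef = 1.0 - math.exp(-dt / self.tau_f)
        h = state["h"] + (self.h_inf(V) - state["h"]) * eh
        f = state["f"] + (self.f_inf(V) - state["f"]) * ef
        fb = mix.fraction_b
        po = (1 - fb) * state["p_a"][io] + fb * state["p_b"][io]
        currents = {
            "IK1": self.g_k1 * self.r_inf(V) * (V - self.EK),
            "Ifast": self.g_fast * self.m_inf(V) * state["h"] * (V - self.E_fast),
            "Iplateau": self.g_ca * self.d_inf(V) * f * (V - self.E_plateau),
            "IKp": self.g_kp * self.x_inf(V) * (V - self.EK),
            "IKr": self.gkr * po * (V - self.EK),
        }
        dvdt = -(sum(currents.values()) + stim)
        return dvdt, {"V": V, "h": h, "f": f, "p_a": p_a, "p_b": p_b}, currents


@runtime_checkable
class IonicModelInterface(Protocol):
    """Structural contract for pluggable ventricular ionic models.

    An implementation must provide ``rest_state(mix)`` returning the
    model's full state at its resting equilibrium, and
    ``step(V, state, dt, stim, mix)`` returning (dV/dt, updated state,
    named currents including "IKr").  With zero stimulus from rest the
    voltage must stay within 0.01 mV of rest for at least a second.
    :class:`SurrogateVentricularModel` is the shipped implementation;
    full ventricular myocyte models plug in the same way.
    """

    def rest_state(self, mix: IsoformMix) -> dict: ...

    def step(self, V: float, state: dict, dt: float, stim: float, mix: IsoformMix): ...


@dataclass
class CellResult:
    """Final-beat record of a paced-cell simulation."""

    time: np.ndarray            # ms within the final beat
    V: np.ndarray               # mV
    occupancy_a: np.ndarray     # (n_samples, 5) isoform-a Markov occupancy
    occupancy_b: np.ndarray
    ikr: np.ndarray             # pA/pF mixture current
    states: tuple[str, ...]
    rest_V: float
    mix: IsoformMix

    @property
    def open_occupancy_a(self) -> np.ndarray:
        return self.occupancy_a[:, self.states.index("O")]

    @property
    def open_occupancy_b(self) -> np.ndarray:
        return self.occupancy_b[:, self.states.index("O")]


def build_sim_table(model: "SurrogateVentricularModel") -> np.ndarray:
    """Combined kernel lookup table: both isoforms' rates plus gate curves."""
    grid = np.arange(
        _kernels.TABLE_V_MIN, _kernels.TABLE_V_MAX + _kernels.TABLE_DV / 2,
        _kernels.TABLE_DV,
    )
    ta = _kernels.build_rate_table(model.scheme, model.params_a)
    tb = _kernels.build_rate_table(model.scheme, model.params_b)
    gates = np.column_stack([
        model.m_inf(grid), model.h_inf(grid), model.d_inf(grid),
        model.f_inf(grid), model.r_inf(grid), model.x_inf(grid),
    ])
    return np.ascontiguousarray(np.hstack([ta, tb, gates]))


def simulate_cell(
    model: SurrogateVentricularModel,
    mix: IsoformMix,
    bcl: float = 1000.0,
    n_beats: int = 30,
    dt_coarse: float = 0.005,
    dt_fine: float = 0.00005,
    stim_amplitude: float = -80.0,
    stim_duration: float = 1.0,
    upstroke_threshold: float = 30.0,
    record_dt: float = 1.0,
) -> CellResult:
    """Pace a single cell and record the final beat.

    Voltage advances by forward Euler; the step drops to ``dt_fine``
    while the stimulus is on or while |dV/dt| of the previous step
    exceeds ``upstroke_threshold`` (the upstroke criterion), and is
    ``dt_coarse`` otherwise.  A zero-amplitude stimulus leaves the cell
    at its resting equilibrium.
    """
    if n_beats < 1:
        raise ValidationError("n_beats must be >= 1")
    rest = model.rest_state(mix)
    V = np.array([rest["V"]])
    h = np.array([rest["h"]])
    f = np.array([rest["f"]])
    pa = rest["p_a"][None, :].copy()
    pb = rest["p_b"][None, :].copy()
    table = build_sim_table(model)
    src, tgt = _kernels.edge_index_arrays()
    n_rec = int(round(bcl / record_dt))
    rec_V = np.empty((n_rec, 1))
    rec_oa = np.empty((n_rec, 5))
    rec_ob = np.empty((n_rec, 5))
    rec_ikr = np.empty(n_rec)
    status = _kernels.run_paced(
        V, h, f, pa, pb,
        mix.fraction_b,
        model.g_k1, model.g_fast, model.g_ca, model.g_kp, model.gkr, model.EK,
        model.E_fast, model.E_plateau, model.tau_h, model.tau_f,
        _kernels.TABLE_V_MIN, 1.0 / _kernels.TABLE_DV, table, src, tgt,
        0.0, stim_amplitude, stim_duration, True,
        bcl, n_beats, dt_coarse, dt_fine, upstroke_threshold,
        record_dt, rec_V, rec_oa, rec_ob, rec_ikr,
    )
    if status == _kernels.STATUS_UNSTABLE:
        raise NumericalError(
            "voltage instability (|V| > 200 mV); reduce dt or stimulus"
        )
    if status == _kernels.STATUS_PROB_LEAK:
        raise NumericalError("Markov probability leak exceeded 1e-6 within a beat")
    return CellResult(
        time=np.arange(n_rec) * record_dt,
        V=rec_V[:, 0],
        occupancy_a=rec_oa,
        occupancy_b=rec_ob,
        ikr=rec_ikr,
        states=model.scheme.states,
        rest_V=rest["V"],
        mix=mix,
    )


def apd(
    time: np.ndarray,
    V: np.ndarray,
    repolarization_fraction: float = 0.9,
    min_amplitude: float = 10.0,
) -> float:
    """Action-potential duration (ms) at a repolarization fraction.

    Measured from the time of maximum dV/dt to the crossing of
    rest + (1 - fraction) * (peak - rest), with linear interpolation at
    the crossing.  APD90 is the default.

    Raises
    ------
    NoAPError
        If the trace has no depolarization exceeding ``min_amplitude``.
    """
    time = np.asarray(time, dtype=float)
    V = np.asarray(V, dtype=float)
    if time.size < 3:
        raise NoAPError("trace too short")
    rest = V[0]
    peak = V.max()
    if peak - rest < min_amplitude:
        raise NoAPError(
            f"no action potential: amplitude {peak - rest:.2f} mV "
            f"< {min_amplitude} mV"
        )
    dvdt = np.diff(V) / np.diff(time)
    i_up = int(np.argmax(dvdt))
    threshold = rest + (1.0 - repolarization_fraction) * (peak - rest)
    i_peak = int(np.argmax(V))
    below = np.nonzero(V[i_peak:] <= threshold)[0]
    if below.size == 0:
        raise NoAPError("trace does not repolarize to the requested fraction")
    j = i_peak + below[0]
    # linear interpolation between samples j-1 and j
    if j == 0:
        t_cross = time[0]
    else:
        v0, v1 = V[j - 1], V[j]
        t0, t1 = time[j - 1], time[j]
        t_cross = t0 if v1 == v0 else t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0)
    return float(t_cross - time[i_up])
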