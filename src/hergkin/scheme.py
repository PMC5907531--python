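"""Gating schemes: states, transitions, and the generator matrix.

Two five-state schemes for the Kv11.1 (hERG) channel are shipped:

* ``mmodel1`` - a linear chain C3 <-> C2 <-> C1 <-> O <-> I: the channel
  must pass through the open state to inactivate.
* ``mmodel2`` - the same chain plus a direct C1 <-> I edge, closing a
  three-state loop {C1, O, I} whose rates are tied together by
  microscopic reversibility.

The master equation is dp/dt = Q p, with the convention that
``Q[j, i]`` holds the i -> j rate for j != i and columns sum to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, ValidationError
from .rates import RateLaw, evaluate_rate


@dataclass(frozen=True)
class Transition:
    """A directed edge of the gating graph.

    ``constrained`` marks an edge whose rate law is not free data but is
    derived from loop closure by :func:`constrain_reversibility`.
    """

    name: str
    source: str
    target: str
    voltage_dependent: bool = True
    constrained: bool = False


@dataclass(frozen=True)
class MarkovScheme:
    """State list plus transition topology of a gating model."""

    name: str
    states: tuple[str, ...]
    open_state: str
    inactivated_states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    loops: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.open_state not in self.states:
            raise ConfigurationError(f"open state {self.open_state!r} not in states")
        names = [t.name for t in self.transitions]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate transition names")
        for t in self.transitions:
            if t.source not in self.states or t.target not in self.states:
                raise ConfigurationError(f"transition {t.name} references unknown state")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def open_index(self) -> int:
        return self.states.index(self.open_state)

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    def transition(self, name: str) -> Transition:
        for t in self.transitions:
            if t.name == name:
                return t
        raise ConfigurationError(f"no transition named {name!r} in scheme {self.name}")

    def free_transitions(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if not t.constrained)

    def edge(self, source: str, target: str) -> Transition:
        for t in self.transitions:
            if t.source == source and t.target == target:
                return t
        raise ConfigurationError(f"no edge {source}->{target} in scheme {self.name}")


def mmodel1() -> MarkovScheme:
    """Linear five-state chain C3 <-> C2 <-> C1 <-> O <-> I.

    Transition names follow the conventional labels: ``ae``/``be`` early
    (de)activation, ``ain``/``bin`` the voltage-independent intermediate
    step, ``aa``/``bb`` late (de)activation, ``bi``/``ai`` inactivation
    and recovery.
    """
    return MarkovScheme(
        name="mmodel1",
        states=("C3", "C2", "C1", "O", "I"),
        open_state="O",
        inactivated_states=("I",),
        transitions=(
            Transition("ae", "C3", "C2"),
            Transition("be", "C2", "C3"),
            Transition("ain", "C2", "C1", voltage_dependent=False),
            Transition("bin", "C1", "C2", voltage_dependent=False),
            Transition("aa", "C1", "O"),
            Transition("bb", "O", "C1"),
            Transition("bi", "O", "I"),
            Transition("ai", "I", "O"),
        ),
    )


def mmodel2() -> MarkovScheme:
    """M-model 1 plus a direct C1 <-> I edge closing the {C1, O, I} loop.

    The forward edge ``ci`` (C1 -> I) is free data; the reverse ``ic``
    (I -> C1) is flagged constrained and must be resolved by
    :func:`constrain_reversibility` before the generator can be built.
    """
    base = mmodel1()
    return MarkovScheme(
        name="mmodel2",
        states=base.states,
        open_state=base.open_state,
        inactivated_states=base.inactivated_states,
        transitions=base.transitions + (
            Transition("ci", "C1", "I"),
            Transition("ic", "I", "C1", constrained=True),
        ),
        loops=(("C1", "O", "I"),),
    )


_SCHEMES = {"mmodel1": mmodel1, "mmodel2": mmodel2}


def get_scheme(name: str) -> MarkovScheme:
    try:
        return _SCHEMES[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown scheme {name!r}; available: {sorted(_SCHEMES)}"
        ) from None


@dataclass(frozen=True)
class ParameterSet:
    """Per-transition rate laws for one scheme and one isoform.

    ``temperature`` records the temperature of validity (K) of the
    kinetic parameters, not a quantity used in rate evaluation.
    """

    scheme_name: str
    isoform: str
    rates: dict[str, RateLaw] = field(default_factory=dict)
    temperature: float = 296.15

    def validate_against(self, scheme: MarkovScheme) -> None:
        if scheme.name != self.scheme_name:
            raise ConfigurationError(
                f"parameter set is for {self.scheme_name!r}, scheme is {scheme.name!r}"
            )
        for t in scheme.free_transitions():
            if t.name not in self.rates:
                raise ConfigurationError(f"missing rate law for transition {t.name!r}")
            if not t.voltage_dependent and self.rates[t.name].beta != 0.0:
                raise ValidationError(
                    f"transition {t.name!r} is voltage-independent but beta != 0"
                )

    def rate(self, name: str) -> RateLaw:
        try:
            return self.rates[name]
        except KeyError:
            raise ConfigurationError(f"missing rate law for transition {name!r}") from None

    def with_rate(self, name: str, law: RateLaw) -> "ParameterSet":
        new = dict(self.rates)
        new[name] = law
        return replace(self, rates=new)

    def with_corrections(self, corrections: dict[str, tuple[float, float]]) -> "ParameterSet":
        """Return a copy with (corr_a, corr_b) applied to named transitions."""
        new = dict(self.rates)
        for name, (ca, cb) in corrections.items():
            new[name] = new[name].with_corrections(corr_a=ca, corr_b=cb)
        return replace(self, rates=new)


def build_generator(scheme: MarkovScheme, params: ParameterSet, V: float) -> np.ndarray:
    """Assemble the generator matrix Q (ms^-1) at membrane potential V.

    Q[j, i] is the i -> j rate for j != i; diagonal entries are set so
    every column sums to zero (probability conservation).  Constrained
    transitions must already be resolved (see
    :func:`constrain_reversibility`).
    """
    params.validate_against(scheme)
    n = scheme.n_states
    Q = np.zeros((n, n))
    for t in scheme.transitions:
        law = params.rate(t.name)
        k = evaluate_rate(law, V)
        i = scheme.state_index(t.source)
        j = scheme.state_index(t.target)
        Q[j, i] += k
        Q[i, i] -= k
    return Q


def _loop_edges(scheme: MarkovScheme, loop: tuple[str, ...]) -> tuple[list[Transition], list[Transition]]:
    """Forward (cyclic order) and backward edge lists of a loop."""
    fwd, bwd = [], []
    k = len(loop)
    for i in range(k):
        s, t = loop[i], loop[(i + 1) % k]
        fwd.append(scheme.edge(s, t))
        bwd.append(scheme.edge(t, s))
    return fwd, bwd


def constrain_reversibility(scheme: MarkovScheme, params: ParameterSet) -> ParameterSet:
    """Resolve constrained edges so every loop obeys detailed balance.

    Around each loop the product of clockwise rates must equal the
    product of counterclockwise rates at every voltage, which for
    exponential rate laws splits into two separate balances: one on the
    prefactors (alphas) and one on the voltage coefficients (betas).
    The constrained edge's law is therefore fully determined by the
    remaining edges of its loop:

        alpha_c = prod(alpha_opposite) / prod(alpha_same_side)
        beta_c  = sum(beta_opposite) - sum(beta_same_side)

    Effective (correction-applied) values of the other edges are used,
    and the derived law carries unit corrections.

    Schemes without loops are returned unchanged.
    """
    if not scheme.loops:
        return params
    out = params
    for loop in scheme.loops:
        fwd, bwd = _loop_edges(scheme, loop)
        constrained = [t for t in fwd + bwd if t.constrained]
        if len(constrained) != 1:
            raise ConfigurationError(
                f"loop {loop} must have exactly one constrained edge, "
                f"found {[t.name for t in constrained]}"
            )
        target = constrained[0]
        same_side, opposite = (fwd, bwd) if target in fwd else (bwd, fwd)
        log_alpha = 0.0
        beta = 0.0
        for t in opposite:
            law = out.rate(t.name)
            log_alpha += math.log(law.effective_alpha)
            beta += law.effective_beta
        for t in same_side:
            if t is target:
                continue
            law = out.rate(t.name)
            log_alpha -= math.log(law.effective_alpha)
            beta -= law.effective_beta
        out = out.with_rate(target.name, RateLaw(alpha=math.exp(log_alpha), beta=beta))
    return out


def loop_closure_ratio(
    scheme: MarkovScheme, params: ParameterSet, V: float, loop: Iterable[str] | None = None
) -> float:
    """Clockwise over counterclockwise rate product around a loop at V.

    Equals 1 (to rounding) after :func:`constrain_reversibility`.
    """
    loops = [tuple(loop)] if loop is not None else list(scheme.loops)
    if not loops:
        raise ConfigurationError("scheme has no loops")
    ratio = 1.0
    for lp in loops:
        fwd, bwd = _loop_edges(scheme, lp)
        log_r = 0.0
        for t in fwd:
            log_r += math.log(evaluate_rate(params.rate(t.name), V))
        for t in bwd:
            log_r -= math.log(evaluate_rate(params.rate(t.name), V))
        ratio *= math.exp(log_r)
    return ratio
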