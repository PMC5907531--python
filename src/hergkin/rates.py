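"""Voltage-dependent transition rates.

Every transition between gating states carries an exponential rate law

    k(V) = a * alpha * exp(b * beta * V)

where ``alpha`` (ms^-1) and ``beta`` (mV^-1) are the base kinetic
parameters and ``a``/``b`` are dimensionless correction factors.  The
base pair may alternatively be derived from transition-state
thermodynamics: alpha = (kB*T/h) * exp(dS/R - dH/(R*T)) and
beta = z*F/(R*T) at temperature T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .constants import (
    BOLTZMANN_J_PER_K,
    FARADAY_C_PER_MOL,
    GAS_CONSTANT_J_PER_MOL_K,
    PLANCK_J_S,
)
from .errors import InvalidParameterError, ValidationError

# exponent magnitude above which evaluation switches to log space so the
# overflow check happens before exp() is taken
_LOG_GUARD = 50.0
_MAX_EXPONENT = 700.0


@dataclass(frozen=True)
class RateLaw:
    """One transition's rate law k(V) = corr_a*alpha*exp(corr_b*beta*V).

    Parameters
    ----------
    alpha : float
        Zero-voltage prefactor, ms^-1.  Must be positive.
    beta : float
        Voltage coefficient, mV^-1.  Zero for voltage-independent
        transitions.
    corr_a, corr_b : float
        Dimensionless multiplicative corrections; the quantities that a
        global fit optimizes while alpha/beta stay frozen at their
        reference values.  ``corr_a`` must be positive.
    """

    alpha: float
    beta: float
    corr_a: float = 1.0
    corr_b: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0 and math.isfinite(self.alpha)):
            raise ValidationError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.corr_a > 0.0 and math.isfinite(self.corr_a)):
            raise ValidationError(f"corr_a must be positive and finite, got {self.corr_a}")
        if not (math.isfinite(self.beta) and math.isfinite(self.corr_b)):
            raise ValidationError("beta and corr_b must be finite")

    @classmethod
    def from_thermodynamics(
        cls, dH: float, dS: float, z: float, T: float,
        corr_a: float = 1.0, corr_b: float = 1.0,
    ) -> "RateLaw":
        """Build a rate law from Eyring transition-state parameters.

        Parameters
        ----------
        dH : float
            Enthalpy change, J/mol.
        dS : float
            Entropy change, J/mol/K.
        z : float
            Effective valence of the moving charge (dimensionless).
        T : float
            Temperature, K.

        Notes
        -----
        The prefactor kB*T/h is in s^-1; division by 1000 converts to
        ms^-1, and F/(R*T) is scaled to mV^-1.
        """
        R = GAS_CONSTANT_J_PER_MOL_K
        alpha = (BOLTZMANN_J_PER_K * T / PLANCK_J_S) * math.exp(dS / R - dH / (R * T)) / 1e3
        beta = z * FARADAY_C_PER_MOL / (R * T) / 1e3
        return cls(alpha=alpha, beta=beta, corr_a=corr_a, corr_b=corr_b)

    @property
    def effective_alpha(self) -> float:
        """corr_a * alpha, the prefactor actually applied."""
        return self.corr_a * self.alpha

    @property
    def effective_beta(self) -> float:
        """corr_b * beta, the voltage coefficient actually applied."""
        return self.corr_b * self.beta

    def with_corrections(self, corr_a: float | None = None, corr_b: float | None = None) -> "RateLaw":
        kw = {}
        if corr_a is not None:
            kw["corr_a"] = corr_a
        if corr_b is not None:
            kw["corr_b"] = corr_b
        return replace(self, **kw)

    def __call__(self, V: float) -> float:
        return evaluate_rate(self, V)


def evaluate_rate(law: RateLaw, V: float) -> float:
    """Evaluate k(V) = corr_a*alpha*exp(corr_b*beta*V) in ms^-1.

    Voltage-independent transitions (beta == 0) return corr_a*alpha for
    any V.  At extreme exponents the evaluation is done in log space so
    overflow is detected and reported instead of silently producing inf.

    Raises
    ------
    InvalidParameterError
        If V is non-finite or the rate overflows a double.
    """
    if not math.isfinite(V):
        raise InvalidParameterError(f"membrane potential must be finite, got {V}")
    exponent = law.corr_b * law.beta * V
    if abs(exponent) > _LOG_GUARD:
        log_k = math.log(law.effective_alpha) + exponent
        if log_k > _MAX_EXPONENT:
            raise InvalidParameterError(
                f"rate overflow: log k = {log_k:.1f} at V = {V} mV "
                f"(alpha={law.alpha}, beta={law.beta})"
            )
        return math.exp(log_k)
    k = law.effective_alpha * math.exp(exponent)
    if not math.isfinite(k):
        raise InvalidParameterError(f"non-finite rate at V = {V} mV")
    return k
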