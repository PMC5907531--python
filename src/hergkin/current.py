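"""Macroscopic current from open-state occupancy.

I_Kr = gKr * pO * (V - EK), with the maximal conductance scaled for
temperature and external potassium:

    gKr = gKr0 * (a*T + b) * sqrt(Ko / 5.4 mM)

The linear temperature factor (a = 1/35 K^-1, b = -55/7) equals exactly
1 at T = 310 K, so gKr0 is the physiological-temperature baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    BATH_K_MM,
    FARADAY_C_PER_MOL,
    GAS_CONSTANT_J_PER_MOL_K,
    PIPETTE_K_MM,
    ROOM_TEMPERATURE_K,
)
from .errors import ValidationError


def nernst_potential(Ki: float, Ko: float, T: float) -> float:
    """Potassium reversal potential EK = (R*T/F) ln(Ko/Ki), in mV.

    Parameters are internal and external K+ in mM and temperature in K.
    """
    if Ki <= 0 or Ko <= 0:
        raise ValidationError(f"concentrations must be positive, got Ki={Ki}, Ko={Ko}")
    return 1e3 * GAS_CONSTANT_J_PER_MOL_K * T / FARADAY_C_PER_MOL * math.log(Ko / Ki)


@dataclass(frozen=True)
class CurrentParams:
    """Conductance and driving-force parameters for I_Kr.

    ``EK`` defaults to the Nernst potential computed from Ki/Ko at T;
    pass an explicit value to override (e.g. a measured reversal).
    """

    gKr0: float = 0.024          # pA/pF/mV, baseline at 310 K
    temp_slope: float = 1.0 / 35.0   # K^-1
    temp_offset: float = -55.0 / 7.0
    Ko: float = BATH_K_MM        # mM
    Ki: float = PIPETTE_K_MM     # mM
    T: float = ROOM_TEMPERATURE_K
    EK: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.gKr0 <= 0:
            raise ValidationError("gKr0 must be positive")
        if self.Ko <= 0 or self.Ki <= 0:
            raise ValidationError("potassium concentrations must be positive")
        if self.temp_slope * self.T + self.temp_offset <= 0:
            raise ValidationError(
                f"temperature factor a*T+b = "
                f"{self.temp_slope * self.T + self.temp_offset:.4f} <= 0 at T={self.T} K; "
                "outside the validity range of the conductance model"
            )
        if math.isnan(self.EK):
            object.__setattr__(
                self, "EK", nernst_potential(self.Ki, self.Ko, self.T)
            )

    def at_temperature(self, T: float) -> "CurrentParams":
        return replace(self, T=T, EK=math.nan)


def conductance(cp: CurrentParams) -> float:
    """Maximal I_Kr conductance gKr (pA/pF/mV) at cp's T and Ko."""
    factor = cp.temp_slope * cp.T + cp.temp_offset
    return cp.gKr0 * factor * math.sqrt(cp.Ko / BATH_K_MM)


def ikr_current(pO, V: float, cp: CurrentParams):
    """Current density I_Kr = gKr * pO * (V - EK), in pA/pF.

    ``pO`` may be a scalar or an array of open probabilities; the result
    has the same shape.
    """
    pO = np.asarray(pO, dtype=float)
    if np.any(pO < -1e-12) or np.any(pO > 1 + 1e-12):
        raise ValidationError("open probability must lie in [0, 1]")
    out = conductance(cp) * pO * (V - cp.EK)
    return float(out) if out.ndim == 0 else out
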