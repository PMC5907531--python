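"""Seeded synthetic datasets for parameter-recovery studies.

No raw recordings are deposited for the experiments the shipped
parameter tables were fitted to, so the fitting machinery is validated
by recovery: simulate the observables from a known "truth" parameter
set, add Gaussian noise of configurable size, and check that the fit
recovers the truth.  The generator emulates what the protocols measure
(normalized tail-current curves, activation points, deactivation time
courses, recovery time constants), not raw amplifier output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .current import CurrentParams
from .errors import ValidationError
from .fitting import Dataset, FitProblem, simulate_observable
from .protocols import (
    VoltageProtocol,
    make_deactivation_protocol,
    make_envelope_protocol,
    make_recovery_protocol,
    make_ssa_protocol,
)
from .scheme import MarkovScheme, ParameterSet


def default_protocol_suite() -> list[tuple[VoltageProtocol, str]]:
    """The four-protocol battery used for global fits."""
    return [
        (make_ssa_protocol(), "ssa"),
        (make_envelope_protocol(), "envelope"),
        (make_deactivation_protocol(), "deactivation"),
        (make_recovery_protocol(), "recovery_tau"),
    ]


@dataclass
class SyntheticDataset:
    """Noisy observables generated from a known truth parameter set."""

    truth: ParameterSet
    scheme: MarkovScheme
    datasets: list[Dataset]
    noise_sd_fraction: float
    seed: int | None
    cp: CurrentParams = field(default_factory=CurrentParams)

    def fit_problem(
        self, base_params: ParameterSet, free: list[tuple[str, str]], **kwargs
    ) -> FitProblem:
        """Assemble a FitProblem targeting these observables."""
        return FitProblem(
            scheme=self.scheme,
            base_params=base_params,
            datasets=self.datasets,
            free=free,
            cp=self.cp,
            **kwargs,
        )


def generate_synthetic_dataset(
    truth: ParameterSet,
    scheme: MarkovScheme,
    protocols: list[tuple[VoltageProtocol, str]] | None = None,
    noise_sd_fraction: float = 0.0,
    seed: int | None = 0,
    cp: CurrentParams | None = None,
    sample_dt: float = 0.5,
    weights: list[float] | None = None,
) -> SyntheticDataset:
    """Simulate each protocol from ``truth`` and add seeded Gaussian noise.

    The noise SD is ``noise_sd_fraction`` times the largest magnitude of
    each dataset's observable (its per-dataset peak).  Zero noise
    reproduces the simulator output exactly; the same seed reproduces
    the identical dataset bit for bit.
    """
    if noise_sd_fraction < 0:
        raise ValidationError("noise_sd_fraction must be >= 0")
    if protocols is None:
        protocols = default_protocol_suite()
    if cp is None:
        cp = CurrentParams()
    if weights is None:
        weights = [1.0] * len(protocols)
    rng = np.random.default_rng(seed)
    datasets = []
    for (protocol, kind), w in zip(protocols, weights):
        obs = simulate_observable(scheme, truth, protocol, kind, cp=cp, sample_dt=sample_dt)
        if noise_sd_fraction > 0:
            sd = noise_sd_fraction * np.abs(obs).max()
            obs = obs + rng.normal(0.0, sd, size=obs.shape)
        datasets.append(Dataset(protocol=protocol, kind=kind, targets=obs, weight=w))
    return SyntheticDataset(
        truth=truth,
        scheme=scheme,
        datasets=datasets,
        noise_sd_fraction=noise_sd_fraction,
        seed=seed,
        cp=cp,
    )
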