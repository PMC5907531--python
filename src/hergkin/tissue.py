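"""Transmural fiber simulation and the pseudo-ECG.

A one-dimensional strand of ventricular cells coupled by a diffusion
term obeys the monodomain cable equation

    dV/dt = D * d2V/dx2 - (I_ion + I_stim) / Cm

solved with an explicit finite-difference scheme and sealed (no-flux)
ends; the stimulus drives the first cell.  The extracellular unipolar
potential at an electrode beyond the distal end is the lead-field sum

    Phi_e(t) = (a^2 sigma_i) / (4 sigma_e) * sum_x (-dVm/dx) * d(1/r)/dx * dx

whose Q-to-T-end width serves as the simulated QT interval.  With the
shipped surrogate ionic model the fiber is electrically homogeneous;
the endo/M/epi region labels are carried so a heterogeneous ionic
model can map cell variants onto them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cell import CellResult, IsoformMix, SurrogateVentricularModel, build_sim_table
from .errors import NumericalError, ValidationError

DEFAULT_REGIONS = (("endo", 1, 60), ("M", 61, 105), ("epi", 106, 165))


@dataclass(frozen=True)
class CableConfig:
    """Geometry, coupling and pacing of the 1-D transmural strand.

    Lengths in cm, times in ms, stimulus in uA/cm^2 (negative =
    depolarizing inward), D in cm^2/ms, Cm in uF/cm^2.  Region bounds
    are 1-based inclusive cell indices.
    """

    n_cells: int = 165
    dx: float = 0.01                  # 100 um
    diffusion: float = 0.00092
    Cm: float = 1.0
    stim_amplitude: float = -300.0
    stim_duration: float = 0.5
    bcl: float = 1000.0
    n_beats: int = 20
    dt_coarse: float = 0.005
    dt_fine: float = 0.00005
    upstroke_threshold: float = 30.0
    record_dt: float = 1.0
    regions: tuple[tuple[str, int, int], ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValidationError("a fiber needs at least 2 cells")
        if self.dt_fine >= self.dt_coarse:
            raise ValidationError("dt_fine must be smaller than dt_coarse")
        covered = []
        for _, lo, hi in self.regions:
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, self.n_cells + 1)):
            raise ValidationError("regions must partition 1..n_cells disjointly")
        # explicit-diffusion stability (CFL): D dt / dx^2 < 1/2
        cfl = self.diffusion * self.dt_coarse / self.dx**2
        if cfl >= 0.5:
            dt_max = 0.5 * self.dx**2 / self.diffusion
            raise ValidationError(
                f"unstable explicit diffusion: D*dt/dx^2 = {cfl:.3f} >= 0.5; "
                f"use dt_coarse < {dt_max:.4g} ms"
            )

    def region_of(self, cell_index: int) -> str:
        """Region label of a 1-based cell index."""
        for name, lo, hi in self.regions:
            if lo <= cell_index <= hi:
                return name
        raise ValidationError(f"cell index {cell_index} outside fiber")


@dataclass
class FiberResult:
    """Final-beat space-time voltage map of a paced fiber."""

    time: np.ndarray        # ms within the final beat
    Vm: np.ndarray          # (n_samples, n_cells) mV
    x: np.ndarray           # cm, cell centers
    config: CableConfig
    mix: IsoformMix
    cell0: CellResult       # proximal-cell detail (occupancies, IKr)


def simulate_fiber(
    model: SurrogateVentricularModel,
    mix: IsoformMix,
    config: CableConfig | None = None,
) -> FiberResult:
    """Pace a 1-D strand of identical cells and record the final beat.

    All cells start from the single-cell resting equilibrium; the
    stimulus is applied to cell 1 only.  Raises
    :class:`NumericalError` with a suggested time step on instability.
    """
    if config is None:
        config = CableConfig()
    n = config.n_cells
    rest = model.rest_state(mix)
    V = np.full(n, rest["V"])
    h = np.full(n, rest["h"])
    f = np.full(n, rest["f"])
    pa = np.tile(rest["p_a"], (n, 1))
    pb = np.tile(rest["p_b"], (n, 1))
    table = build_sim_table(model)
    src, tgt = _kernels.edge_index_arrays()
    n_rec = int(round(config.bcl / config.record_dt))
    rec_V = np.empty((n_rec, n))
    rec_oa = np.empty((n_rec, 5))
    rec_ob = np.empty((n_rec, 5))
    rec_ikr = np.empty(n_rec)
    status = _kernels.run_paced(
        V, h, f, pa, pb,
        mix.fraction_b,
        model.g_k1, model.g_fast, model.g_ca, model.g_kp, model.gkr, model.EK,
        model.E_fast, model.E_plateau, model.tau_h, model.tau_f,
        _kernels.TABLE_V_MIN, 1.0 / _kernels.TABLE_DV, table, src, tgt,
        config.diffusion / config.dx**2 / config.Cm,
        config.stim_amplitude / config.Cm, config.stim_duration, True,
        config.bcl, config.n_beats, config.dt_coarse, config.dt_fine,
        config.upstroke_threshold,
        config.record_dt, rec_V, rec_oa, rec_ob, rec_ikr,
    )
    if status == _kernels.STATUS_UNSTABLE:
        dt_max = 0.5 * config.dx**2 / config.diffusion
        raise NumericalError(
            f"fiber integration unstable; try dt_coarse <= {min(dt_max, config.dt_coarse / 2):.4g} ms"
        )
    if status == _kernels.STATUS_PROB_LEAK:
        raise NumericalError("Markov probability leak exceeded 1e-6 within a beat")
    t = np.arange(n_rec) * config.record_dt
    cell0 = CellResult(
        time=t, V=rec_V[:, 0], occupancy_a=rec_oa, occupancy_b=rec_ob,
        ikr=rec_ikr, states=model.scheme.states, rest_V=rest["V"], mix=mix,
    )
    x = (np.arange(n) + 0.5) * config.dx
    return FiberResult(time=t, Vm=rec_V, x=x, config=config, mix=mix, cell0=cell0)


@dataclass(frozen=True)
class ECGGeometry:
    """Volume-conductor factors and electrode placement for the pseudo-ECG.

    Conductivities enter only through the ratio sigma_i/sigma_e; with
    the default ratio of 1 and the small fiber radius the potential is
    in arbitrary units (only shapes and intervals are meaningful).  The
    electrode sits on the fiber axis ``electrode_gap`` cm beyond the
    distal end unless explicit coordinates are given.
    """

    sigma_i: float = 1.0
    sigma_e: float = 1.0
    radius: float = 0.0011          # cm
    electrode_gap: float = 2.0      # cm beyond the distal end, on axis
    electrode_xyz: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma_i <= 0 or self.sigma_e <= 0 or self.radius <= 0:
            raise ValidationError("conductivities and radius must be positive")

    def electrode_position(self, x: np.ndarray) -> np.ndarray:
        if self.electrode_xyz is not None:
            return np.asarray(self.electrode_xyz, dtype=float)
        return np.array([x[-1] + self.electrode_gap, 0.0, 0.0])


def pseudo_ecg(
    Vm: np.ndarray, x: np.ndarray, geometry: ECGGeometry | None = None
) -> np.ndarray:
    """Extracellular potential time series from a fiber voltage map.

    ``Vm`` has shape (n_samples, n_cells); ``x`` are cell centers (cm).
    The integrand (-dVm/dx) * d(1/r)/dx is discretized with central
    differences in the interior and one-sided differences at the ends.
    """
    if geometry is None:
        geometry = ECGGeometry()
    Vm = np.asarray(Vm, dtype=float)
    x = np.asarray(x, dtype=float)
    if Vm.ndim != 2 or Vm.shape[1] != x.size:
        raise ValidationError("Vm must be (n_samples, n_cells) matching x")
    ex, ey, ez = geometry.electrode_position(x)
    r = np.sqrt((x - ex) ** 2 + ey**2 + ez**2)
    if np.any(r < 1e-9):
        raise ValidationError("electrode coincides with a fiber cell")
    dx = float(np.mean(np.diff(x)))
    # d(1/r)/dx along the fiber axis
    dinvr = -(x - ex) / r**3
    grad = np.empty_like(Vm)
    grad[:, 1:-1] = (Vm[:, 2:] - Vm[:, :-2]) / (2 * dx)
    grad[:, 0] = (Vm[:, 1] - Vm[:, 0]) / dx
    grad[:, -1] = (Vm[:, -1] - Vm[:, -2]) / dx
    scale = geometry.radius**2 * geometry.sigma_i / (4.0 * geometry.sigma_e)
    return scale * (-grad) @ dinvr * dx


def qt_interval(
    time: np.ndarray,
    phi_e: np.ndarray,
    baseline_tolerance: float = 0.02,
) -> float:
    """Width (ms) of the deflection complex of one beat's pseudo-ECG.

    Baseline is the initial potential; the interval runs from the first
    departure beyond ``baseline_tolerance`` times the maximum absolute
    deflection to the last sustained return within it.  Intended for
    ordering comparisons (QT shortening/prolongation), not absolute QT.

    Raises
    ------
    ValidationError
        If the signal never leaves baseline.
    """
    time = np.asarray(time, dtype=float)
    phi = np.asarray(phi_e, dtype=float)
    dev = np.abs(phi - phi[0])
    top = dev.max()
    if top <= 0:
        raise ValidationError("no deflection detected in pseudo-ECG")
    thresh = baseline_tolerance * top
    above = np.nonzero(dev > thresh)[0]
    if above.size == 0:
        raise ValidationError("no deflection beyond baseline tolerance")
    return float(time[above[-1]] - time[above[0]])
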