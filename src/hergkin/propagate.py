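"""Exact propagation of state probabilities over constant-voltage segments.

For a time-homogeneous generator Q the master equation has the closed
form p(t) = exp(Q t) p0.  Segments of the step protocols are exactly
that case, so propagation is free of ODE-solver tolerance: the only
approximation left is floating-point rounding.

The fast path diagonalizes Q (5x5, generically diagonalizable) and
evaluates all sample times at once; if the eigenbasis is ill-conditioned
the code falls back to repeated multiplication by expm(Q * dt).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm, null_space

from .errors import NumericalError

_CONSERVATION_TOL = 1e-9
_EIG_COND_LIMIT = 1e10


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of the generator Q.

    Solves Q p = 0 with sum(p) = 1 via the null space of Q.  For an
    irreducible generator the null space is one-dimensional and the
    (normalized) solution is the unique stationary distribution.

    Raises
    ------
    NumericalError
        If the null space is not one-dimensional (reducible or
        defective Q) or the residual is large.
    """
    Q = np.asarray(Q, dtype=float)
    ns = null_space(Q)
    if ns.shape[1] != 1:
        raise NumericalError(
            f"generator null space has dimension {ns.shape[1]}; "
            "expected 1 (is the chain irreducible?)"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if p.min() < -1e-12:
        raise NumericalError(f"negative steady-state occupancy: min = {p.min():.3e}")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    resid = np.abs(Q @ p).max()
    if resid > 1e-10:
        raise NumericalError(f"steady-state residual ||Q p||_inf = {resid:.3e}")
    return p


def _check_conservation(P: np.ndarray) -> np.ndarray:
    sums = P.sum(axis=1)
    err = np.abs(sums - 1.0).max()
    if err > _CONSERVATION_TOL:
        raise NumericalError(f"probability leak {err:.3e} exceeds {_CONSERVATION_TOL}")
    # renormalize rounding drift so long protocols do not accumulate it
    P = P / sums[:, None]
    return np.clip(P, 0.0, 1.0)


def propagate_segment(
    p0: np.ndarray, Q: np.ndarray, duration: float, sample_dt: float
) -> np.ndarray:
    """Propagate p0 under constant Q, sampled every ``sample_dt`` ms.

    Returns an array of shape (n_samples, n_states) with row k equal to
    exp(Q * k * sample_dt) p0; the first row is p0 and the last row is
    at t = duration (duration must be an integer multiple of sample_dt
    to within rounding).  duration = 0 returns p0 alone.
    """
    p0 = np.asarray(p0, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be positive")
    n_steps = int(round(duration / sample_dt))
    if abs(n_steps * sample_dt - duration) > 1e-6 * max(1.0, duration):
        raise ValueError(
            f"duration {duration} is not a multiple of sample_dt {sample_dt}"
        )
    if n_steps == 0:
        return p0[None, :].copy()
    t = np.arange(n_steps + 1) * sample_dt
    P = _eig_propagate(p0, Q, t)
    if P is None:
        P = _expm_step_propagate(p0, Q, sample_dt, n_steps)
    return _check_conservation(P)


def _eig_propagate(p0: np.ndarray, Q: np.ndarray, t: np.ndarray) -> np.ndarray | None:
    """All-times propagation through the eigenbasis; None if ill-conditioned."""
    try:
        w, V = np.linalg.eig(Q)
    except np.linalg.LinAlgError:
        return None
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > _EIG_COND_LIMIT:
        return None
    c = np.linalg.solve(V, p0.astype(complex))
    # p(t_k) = V @ (exp(w t_k) * c)
    P = (V @ (np.exp(np.outer(w, t)) * c[:, None])).T
    P = np.real(P)
    if not np.all(np.isfinite(P)):
        return None
    return P


def _expm_step_propagate(
    p0: np.ndarray, Q: np.ndarray, sample_dt: float, n_steps: int
) -> np.ndarray:
    E = expm(Q * sample_dt)
    P = np.empty((n_steps + 1, p0.size))
    P[0] = p0
    p = p0.copy()
    for k in range(n_steps):
        p = E @ p
        P[k + 1] = p
    return P
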