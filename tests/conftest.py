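import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hergkin import (
    CurrentParams,
    load_builtin_parameters,
    mmodel1,
    mmodel2,
)


@pytest.fixture(scope="session")
def m1():
    return mmodel1()


@pytest.fixture(scope="session")
def m2():
    return mmodel2()


@pytest.fixture(scope="session")
def p1a():
    return load_builtin_parameters("mmodel1", "hERG1a")


@pytest.fixture(scope="session")
def p1b():
    return load_builtin_parameters("mmodel1", "hERG1b")


@pytest.fixture(scope="session")
def p2a():
    return load_builtin_parameters("mmodel2", "hERG1a")


@pytest.fixture(scope="session")
def p2b():
    return load_builtin_parameters("mmodel2", "hERG1b")


@pytest.fixture(scope="session")
def room_cp():
    return CurrentParams()


def euler_endpoint(p0: np.ndarray, Q: np.ndarray, duration: float, dt: float = 1e-4) -> np.ndarray:
    """Explicit-Euler oracle: state at segment end via the one-step matrix.

    The Euler iterate after n steps is (I + dt*Q)^n p0; the matrix power
    is computed by binary exponentiation, which reproduces the looped
    iteration to floating-point rounding while staying tractable for
    millions of steps.
    """
    n = int(round(duration / dt))
    M = np.eye(Q.shape[0]) + dt * Q
    return np.linalg.matrix_power(M, n) @ p0
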