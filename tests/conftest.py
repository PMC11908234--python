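import numpy as np
import pytest

from hbcregen import CellCycleParams, PartitionParams


@pytest.fixture
def printed_cycle_params() -> CellCycleParams:
    """The fitted regeneration-model constants."""
    return CellCycleParams(kmax=2.27, k2=1.33, k3=6.0, gamma=0.06, K=0.4, h=2.0, tau=0.8)


@pytest.fixture
def printed_partition_params() -> PartitionParams:
    """The fitted partitioning-mixture parameters."""
    return PartitionParams(ps=0.45, sigma=0.09, pb=0.23)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def rk4_trajectory(params: CellCycleParams, y0: np.ndarray, t0: float,
                   t_eval: np.ndarray, dt: float = 1e-4) -> np.ndarray:
    """Independent fixed-step RK4 integrator used as the ODE oracle.

    Integrates from t0 and returns the state at each requested time
    (each t in t_eval must be >= t0 and land on the step grid to within
    rounding).
    """
    kmax, k2, k3, gamma, K, h = (params.kmax, params.k2, params.k3,
                                 params.gamma, params.K, params.h)

    def f(y):
        h1, h2, h3, d = y
        k1 = kmax / (1.0 + (d / K) ** h)
        return np.array([-k1 * h1 + k3 * h3, k1 * h1 - k2 * h2,
                         k2 * h2 - k3 * h3, k3 * h3 - gamma * d])

    y = np.array(y0, dtype=float)
    t = t0
    out = []
    for target in t_eval:
        n = int(round((target - t) / dt))
        for _ in range(n):
            a = f(y)
            b = f(y + dt / 2 * a)
            c = f(y + dt / 2 * b)
            d_ = f(y + dt * c)
            y = y + dt / 6 * (a + 2 * b + 2 * c + d_)
        t = t + n * dt
        out.append(y.copy())
    return np.array(out)
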