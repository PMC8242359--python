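import numpy as np
import pytest

from clostkin.dose_response import SurvivalTable
from clostkin.ferm_kinetics import FermentationState, KineticParams
from clostkin.synthetic_data import load_fixture


@pytest.fixture(scope="session")
def table2() -> dict[str, SurvivalTable]:
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table4_params() -> KineticParams:
    return load_fixture("table4")


@pytest.fixture(scope="session")
def reference_initial() -> FermentationState:
    """High-glucose batch start: 180 g/L glucose, 0.1 g/L DCW inoculum."""
    return FermentationState(t=0.0, X=0.1, S=180.0, P_Ba=0.0, P_Aa=0.0)


def rk4_integrate(params: KineticParams, initial: FermentationState,
                  t_end: float, h: float, t_eval: np.ndarray) -> np.ndarray:
    """Fixed-step classical RK4 oracle, independent of scipy's solvers.

    Returns the state matrix (len(t_eval), 4) by linear interpolation of the
    fixed grid onto t_eval.
    """
    from clostkin.ferm_kinetics import ode_rhs

    def f(y):
        state = FermentationState(t=0.0, X=max(y[0], 0.0), S=max(y[1], 0.0),
                                  P_Ba=max(y[2], 0.0), P_Aa=max(y[3], 0.0))
        return np.array(ode_rhs(params, state))

    n = int(round(t_end / h))
    ts = np.linspace(0.0, n * h, n + 1)
    ys = np.empty((n + 1, 4))
    y = initial.as_vector().astype(float)
    ys[0] = y
    for k in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.clip(y, 0.0, None)
        ys[k + 1] = y
    out = np.empty((len(t_eval), 4))
    for j in range(4):
        out[:, j] = np.interp(t_eval, ts, ys[:, j])
    return out
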