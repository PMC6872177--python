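import dataclasses

import numpy as np
import pytest

import erythropy as e
from erythropy.simulate import DEFAULT_TRUE_PARAMETERS

#: m = 8 timepoints used by the recovery and selection studies
EIGHT_TIMEPOINTS = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0)


@pytest.fixture(scope="session")
def true_params():
    return DEFAULT_TRUE_PARAMETERS


@pytest.fixture(scope="session")
def noiseless_params():
    return dataclasses.replace(
        DEFAULT_TRUE_PARAMETERS, error=e.ErrorParameters(0.0, 0.0)
    )


@pytest.fixture(scope="session")
def noisy_dataset(true_params):
    return e.simulate_kinetics(
        e.KineticsDesign(timepoints=EIGHT_TIMEPOINTS, true_params=true_params, seed=7)
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_params):
    return e.simulate_kinetics(
        e.KineticsDesign(
            timepoints=EIGHT_TIMEPOINTS, true_params=noiseless_params, seed=8
        )
    )


@pytest.fixture(scope="session")
def expression_pair():
    return e.simulate_expression(e.ExpressionDesign(seed=42))


def rk4_solve(params, y0, t_end, h=0.01):
    """Fixed-step fourth-order Runge-Kutta oracle for the compartment ODE.

    Vectorized over a batch: ``params`` is (5,) or (5, n) and ``y0`` is
    (3,) or (3, n).
    """
    p = np.atleast_2d(np.asarray(params, dtype=float).T).T  # (5, n)
    y = np.array(np.atleast_2d(np.asarray(y0, dtype=float).T).T, dtype=float)
    rho_S, delta_SC, rho_C, delta_CB, rho_B = p

    def rhs(y):
        S, C, B = y
        return np.array(
            [
                rho_S * S - delta_SC * S,
                rho_C * C + delta_SC * S - delta_CB * C,
                rho_B * B + delta_CB * C,
            ]
        )

    n_steps = int(round(t_end / h))
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y.squeeze()
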