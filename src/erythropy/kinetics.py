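"""Three-compartment linear ODE model of in vitro erythroid differentiation.

The model tracks three cell populations: self-renewing progenitors ``S``,
committed progenitors ``C`` and differentiated cells ``B``::

    dS/dt = rho_S * S - delta_SC * S
    dC/dt = rho_C * C + delta_SC * S - delta_CB * C
    dB/dt = rho_B * B + delta_CB * C

where ``rho_i`` is the net proliferation rate of compartment *i* (any sign)
and ``delta_ij >= 0`` is the differentiation rate of cell type *i* into cell
type *j*.  All times are in hours and rates in 1/h.

The system is lower-triangular, so it admits a closed-form solution built
from divided differences of the exponential; the implementation below is
numerically stable through eigenvalue collisions (removable singularities)
and is validated against a high-accuracy numerical integrator in the tests.

Two culture media define two dynamic regimes:

* ``self_renewal`` (LM1): only S cells are present and no differentiation
  occurs before induction, so the dynamics reduce to ``dS/dt = rho_S * S``.
* ``differentiation`` (DM17): the full three-compartment system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedFractionError,
)

__all__ = [
    "DynamicParameters",
    "CompartmentState",
    "InitialCondition",
    "SELF_RENEWAL",
    "DIFFERENTIATION",
    "solve_compartments",
    "predict_observables",
    "fix_delta_SC",
]

SELF_RENEWAL = "self_renewal"
DIFFERENTIATION = "differentiation"
MEDIA = (SELF_RENEWAL, DIFFERENTIATION)

#: Default residual fraction of self-renewing cells used by :func:`fix_delta_SC`.
DEFAULT_EPSILON = 0.01
#: Default clearance horizon (hours): no self-renewing cells remain after 2 days.
DEFAULT_CLEARANCE_T = 48.0


@dataclass(frozen=True)
class DynamicParameters:
    """The five dynamic rates (1/h) of the compartment model.

    ``rho_S``, ``rho_C``, ``rho_B`` are net proliferation rates and may be
    negative (net death); ``delta_SC`` and ``delta_CB`` are differentiation
    rates and must be non-negative.
    """

    rho_S: float
    delta_SC: float
    rho_C: float
    delta_CB: float
    rho_B: float

    def __post_init__(self):
        vals = (self.rho_S, self.delta_SC, self.rho_C, self.delta_CB, self.rho_B)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite dynamic parameters: {vals}")
        if self.delta_SC < 0 or self.delta_CB < 0:
            raise InvalidParameterError(
                "differentiation rates delta_SC and delta_CB must be >= 0, got "
                f"delta_SC={self.delta_SC}, delta_CB={self.delta_CB}"
            )

    def with_delta_SC(self, value: float) -> "DynamicParameters":
        return replace(self, delta_SC=value)


@dataclass(frozen=True)
class CompartmentState:
    """Population sizes of the three compartments at time ``t`` (hours)."""

    S: float
    C: float
    B: float
    t: float

    @property
    def total(self) -> float:
        return self.S + self.C + self.B


@dataclass(frozen=True)
class InitialCondition:
    """Initial state and culture medium.

    In self-renewal medium the culture contains only S cells, so ``C`` and
    ``B`` must both be zero at t = 0.
    """

    y0: CompartmentState
    medium: str = DIFFERENTIATION

    def __post_init__(self):
        if self.medium not in MEDIA:
            raise InvalidParameterError(f"unknown medium {self.medium!r}")
        if min(self.y0.S, self.y0.C, self.y0.B) < 0:
            raise InvalidInputError(f"negative initial populations: {self.y0}")
        if self.medium == SELF_RENEWAL and (self.y0.C != 0 or self.y0.B != 0):
            raise InvalidInputError(
                "self-renewal medium holds only S cells: C(0) = B(0) = 0 required"
            )


def _phi1(z: np.ndarray) -> np.ndarray:
    """(e^z - 1) / z with the limit 1 at z = 0."""
    z = np.asarray(z, dtype=float)
    out = np.ones_like(z)
    nz = np.abs(z) > 1e-14
    out[nz] = np.expm1(z[nz]) / z[nz]
    return out


def _phi1_prime(z: np.ndarray) -> np.ndarray:
    """d/dz [(e^z - 1)/z]; series near 0 to avoid cancellation."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 0.1
    zs = z[small]
    # phi1'(z) = sum_{k>=0} (k+1)/(k+2)! z^k
    acc = np.zeros_like(zs)
    term = np.ones_like(zs)
    fact = 1.0
    for k in range(0, 10):
        fact *= k + 2
        acc += (k + 1) / fact * term
        term = term * zs
    out[small] = acc
    zb = z[~small]
    out[~small] = (np.exp(zb) * (zb - 1.0) + 1.0) / zb**2
    return out


def _phi2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """First divided difference of phi1 at (u, v), stable for u ~ v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    diff = u - v
    close = np.abs(diff) < 1e-6 * np.maximum(1.0, np.maximum(np.abs(u), np.abs(v)))
    out = np.empty(np.broadcast(u, v).shape)
    mid = 0.5 * (u + v)
    out[close] = _phi1_prime(np.broadcast_to(mid, out.shape)[close])
    if np.any(~close):
        ub = np.broadcast_to(u, out.shape)[~close]
        vb = np.broadcast_to(v, out.shape)[~close]
        out[~close] = (_phi1(ub) - _phi1(vb)) / (ub - vb)
    return out


def _dd1(x: float, y: float, t: np.ndarray) -> np.ndarray:
    """First divided difference of s -> e^{s t} at nodes (x, y)."""
    return t * np.exp(y * t) * _phi1((x - y) * t)


def _dd2(a: float, b: float, c: float, t: np.ndarray) -> np.ndarray:
    """Second divided difference of s -> e^{s t} at nodes (a, b, c)."""
    return t**2 * np.exp(c * t) * _phi2((a - c) * t, (b - c) * t)


def solve_compartments(
    params: DynamicParameters,
    init: InitialCondition,
    times,
) -> list[CompartmentState]:
    """Solve the compartment ODE exactly at the requested times.

    Parameters
    ----------
    params : DynamicParameters
        The five rates.  In self-renewal medium ``delta_SC`` is treated as 0
        (no differentiation before induction).
    init : InitialCondition
        Non-negative initial populations and the culture medium.
    times : array-like of float
        Sorted, non-negative times in hours.

    Returns
    -------
    list of CompartmentState
        One state per requested time, in order.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("times must be a non-empty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise InvalidInputError("times must be sorted and non-negative")
    S, C, B = _solve_arrays(params, init, t)
    return [CompartmentState(s, c, b, ti) for s, c, b, ti in zip(S, C, B, t)]


def _solve_arrays(params, init, t):
    """Vectorized closed-form solution; returns (S, C, B) arrays over t."""
    s0, c0, b0 = init.y0.S, init.y0.C, init.y0.B
    if init.medium == SELF_RENEWAL:
        S = s0 * np.exp(params.rho_S * t)
        return S, np.zeros_like(S), np.zeros_like(S)
    a = params.rho_S - params.delta_SC
    b = params.rho_C - params.delta_CB
    c = params.rho_B
    S = s0 * np.exp(a * t)
    C = c0 * np.exp(b * t) + params.delta_SC * s0 * _dd1(a, b, t)
    B = (
        b0 * np.exp(c * t)
        + params.delta_CB * c0 * _dd1(b, c, t)
        + params.delta_CB * params.delta_SC * s0 * _dd2(a, b, c, t)
    )
    return S, C, B


def predict_observables(
    params: DynamicParameters,
    init: InitialCondition,
    times,
) -> list[tuple[float, float]]:
    """Model predictions for the two experimental observables.

    Observable 1 is the total number of live cells ``S + C + B``; observable
    2 is the percentage of differentiated cells ``100 * B / (S + C + B)``.
    The percentage is only meaningful in differentiation medium (in
    self-renewal medium it is identically 0 since only S cells are present).
    """
    t = np.asarray(times, dtype=float)
    total, pct = _predict_arrays(params, init, t)
    return list(zip(total.tolist(), pct.tolist()))


def _predict_arrays(params, init, t):
    S, C, B = _solve_arrays(params, init, t)
    total = S + C + B
    if np.any(total <= 0):
        bad = t[total <= 0]
        raise UndefinedFractionError(
            f"total population is zero at t = {bad.tolist()}; "
            "the differentiated fraction is undefined"
        )
    pct = 100.0 * B / total
    return total, pct


def _solve_raw(rho_S, delta_SC, rho_C, delta_CB, rho_B, s0, t):
    """Closed-form (S, C, B) for an S-only initial condition; no validation."""
    a = rho_S - delta_SC
    b = rho_C - delta_CB
    c = rho_B
    S = s0 * np.exp(a * t)
    C = delta_SC * s0 * _dd1(a, b, t)
    B = delta_CB * delta_SC * s0 * _dd2(a, b, c, t)
    return S, C, B


def fix_delta_SC(
    rho_S: float,
    epsilon: float = DEFAULT_EPSILON,
    T: float = DEFAULT_CLEARANCE_T,
    warn: bool = True,
) -> float:
    """Differentiation rate delta_SC implied by the S-clearance constraint.

    Experimentally, essentially no self-renewing cells remain after the
    clearance horizon ``T`` (2 days by default); delta_SC is therefore not a
    free parameter but is tied to rho_S by requiring that the S compartment
    decays to a residual fraction ``epsilon`` of its initial size:
    ``S(T)/S(0) = epsilon`` under ``dS/dt = (rho_S - delta_SC) S``, i.e. ::

        delta_SC = rho_S + ln(1/epsilon) / T

    Increasing in ``rho_S`` (faster proliferation requires faster exit) and
    decreasing in ``epsilon``.  A negative result is clamped to 0 with a
    warning since differentiation rates cannot be negative.
    """
    if not (0 < epsilon <= 1):
        raise InvalidParameterError(f"epsilon must be in (0, 1], got {epsilon}")
    if T <= 0:
        raise InvalidParameterError(f"clearance horizon T must be > 0, got {T}")
    if not math.isfinite(rho_S):
        raise InvalidParameterError(f"rho_S must be finite, got {rho_S}")
    delta = rho_S + math.log(1.0 / epsilon) / T
    if delta < 0:
        if warn:
            warnings.warn(
                f"implied delta_SC = {delta:.4g} < 0; clamping to 0",
                RuntimeWarning,
                stacklevel=2,
            )
        return 0.0
    return delta
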