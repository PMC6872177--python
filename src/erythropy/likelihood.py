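"""Maximum-likelihood fitting of the compartment model to kinetics data.

The observation model is Gaussian with a standard deviation proportional to
the model prediction (multiplicative noise)::

    y_{i,j,k} ~ Normal(f_i(t_j, y0, theta),  b_i * f_i(t_j, y0, theta))

where ``i`` indexes the observable (1 = live-cell count, 2 = percent
differentiated), ``j`` the timepoint, ``k`` the replicate, and ``b_i > 0``
is a dimensionless error parameter.  Dropping the constant ``n log(2 pi)``,
minus twice the log-likelihood is ::

    -2 log L = sum_{i,j,k} [ ((y_{i,j,k} - f_i) / (b_i f_i))^2
                             + 2 log(b_i f_i) ]

which is minimized over bounded parameters with scipy's truncated-Newton
method from many random starting points (multistart), so the global optimum
is found reliably and reproducibly for a given seed.

Of the seven parameters (five rates + b1, b2), six are estimable: delta_SC
is tied to rho_S through the S-compartment clearance constraint
(:func:`erythropy.kinetics.fix_delta_SC`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    InvalidInputError,
    InvalidParameterError,
)
from .kinetics import (
    DEFAULT_CLEARANCE_T,
    DEFAULT_EPSILON,
    DIFFERENTIATION,
    SELF_RENEWAL,
    CompartmentState,
    DynamicParameters,
    InitialCondition,
    _predict_arrays,
    fix_delta_SC,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorParameters",
    "ParameterSet",
    "KineticsDataset",
    "FitResult",
    "FREE_PARAMETER_NAMES",
    "DEFAULT_BOUNDS",
    "neg_log_likelihood",
    "fit",
    "profile_likelihood",
    "KineticsMLE",
]

#: Observable labels used in kinetics tables.
LIVE_CELLS = "live_cells"
PCT_DIFFERENTIATED = "pct_differentiated"
OBSERVABLES = (LIVE_CELLS, PCT_DIFFERENTIATED)

#: The six estimable parameters, in canonical order.
FREE_PARAMETER_NAMES = ("rho_S", "rho_C", "delta_CB", "rho_B", "b1", "b2")

#: Default optimizer bounds: rates cover doubling/death times down to ~1.4 h,
#: error scales from 0.1% to 200% of the prediction.
DEFAULT_BOUNDS = {
    "rho_S": (-0.5, 0.5),
    "rho_C": (-0.5, 0.5),
    "delta_CB": (0.0, 1.0),
    "rho_B": (-0.5, 0.5),
    "b1": (1e-3, 2.0),
    "b2": (1e-3, 2.0),
}


@dataclass(frozen=True)
class ErrorParameters:
    """Dimensionless multiplicative error scales, one per observable.

    Must be positive for the likelihood (standard deviations ``b_i * f_i``);
    the value 0 is admitted only as the noiseless limit used by the
    simulator, where the likelihood is undefined (evaluates to inf).
    """

    b1: float
    b2: float

    def __post_init__(self):
        if not (self.b1 >= 0 and self.b2 >= 0):
            raise InvalidParameterError(
                f"error parameters must be >= 0, got b1={self.b1}, b2={self.b2}"
            )


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector: five dynamic rates plus two error scales.

    Six components are estimable (rho_S, rho_C, delta_CB, rho_B, b1, b2);
    delta_SC is determined by rho_S via the clearance constraint.
    """

    dynamic: DynamicParameters
    error: ErrorParameters

    def free_values(self) -> np.ndarray:
        """The six estimable components in canonical order."""
        d, e = self.dynamic, self.error
        return np.array([d.rho_S, d.rho_C, d.delta_CB, d.rho_B, e.b1, e.b2])

    @staticmethod
    def from_free_values(
        values,
        epsilon: float = DEFAULT_EPSILON,
        clearance_T: float = DEFAULT_CLEARANCE_T,
    ) -> "ParameterSet":
        """Build a ParameterSet from the six estimable components.

        delta_SC is computed from rho_S via the clearance constraint.
        """
        return _build_parameter_set(values, epsilon, clearance_T)


def default_anchor(
    epsilon: float = DEFAULT_EPSILON, clearance_T: float = DEFAULT_CLEARANCE_T
) -> ParameterSet:
    """A neutral, biologically plausible starting parameter set."""
    return ParameterSet(
        dynamic=DynamicParameters(
            rho_S=0.02,
            delta_SC=fix_delta_SC(0.02, epsilon, clearance_T),
            rho_C=0.02,
            delta_CB=0.05,
            rho_B=0.01,
        ),
        error=ErrorParameters(0.1, 0.1),
    )


@dataclass
class KineticsDataset:
    """Kinetics observations y_{i,j,k} with medium/condition labels.

    ``data`` is a long-format table with columns (condition, medium, time_h,
    replicate, observable, value).  ``y0`` maps each medium present in the
    table to the initial number of (self-renewing) cells seeded at t = 0.
    """

    data: pd.DataFrame
    y0: dict[str, float]
    condition: str = "control"
    _groups: list = field(default=None, repr=False, compare=False)

    REQUIRED_COLUMNS = ("condition", "medium", "time_h", "replicate", "observable", "value")

    def __post_init__(self):
        missing = set(self.REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise InvalidInputError(f"kinetics table missing columns: {sorted(missing)}")
        bad_obs = set(self.data["observable"]) - set(OBSERVABLES)
        if bad_obs:
            raise InvalidInputError(f"unknown observables: {sorted(bad_obs)}")
        pct = self.data.loc[self.data["observable"] == PCT_DIFFERENTIATED, "value"]
        if len(pct) and ((pct < 0).any() or (pct > 100).any()):
            raise InvalidInputError("percent-differentiated values must lie in [0, 100]")
        sr = self.data["medium"] == SELF_RENEWAL
        if (self.data.loc[sr, "observable"] == PCT_DIFFERENTIATED).any():
            raise InvalidInputError(
                "percent differentiated is only defined in differentiation medium"
            )
        for medium in self.data["medium"].unique():
            if medium not in self.y0:
                raise InvalidInputError(f"no initial condition y0 for medium {medium!r}")

    @property
    def n_obs(self) -> int:
        """Total number of scalar observations."""
        return len(self.data)

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def groups(self):
        """Cached (medium, observable, times, values) blocks for fast likelihood."""
        if self._groups is None:
            blocks = []
            for (medium, obs), sub in self.data.groupby(["medium", "observable"], sort=True):
                blocks.append(
                    (
                        medium,
                        obs,
                        sub["time_h"].to_numpy(dtype=float),
                        sub["value"].to_numpy(dtype=float),
                    )
                )
            self._groups = blocks
        return self._groups

    def initial_condition(self, medium: str) -> InitialCondition:
        return InitialCondition(
            y0=CompartmentState(S=self.y0[medium], C=0.0, B=0.0, t=0.0),
            medium=medium,
        )

    def fast_blocks(self):
        """Flattened arrays precomputed for the compiled likelihood kernel.

        Returns ``(sr_t, sr_y, sr_s0, dm_t, dm_s0, live_idx, live_y,
        pct_idx, pct_y)``: self-renewal observations, the unique
        differentiation-medium timepoints, and per-observable index maps
        into them, so the ODE is solved once per evaluation.
        """
        if getattr(self, "_fast_blocks", None) is None:
            empty = np.empty(0, dtype=float)
            sr_t, sr_y, sr_s0 = empty, empty, 0.0
            dm = {}
            for medium, obs, times, values in self.groups():
                if medium == SELF_RENEWAL:
                    sr_t, sr_y = times, values
                    sr_s0 = float(self.y0[medium])
                else:
                    dm[obs] = (times, values)
            if dm:
                dm_s0 = float(self.y0[DIFFERENTIATION])
                dm_t = np.unique(np.concatenate([t for t, _ in dm.values()]))
                pos = {t: i for i, t in enumerate(dm_t)}

                def index_of(obs):
                    if obs not in dm:
                        return np.empty(0, dtype=np.intp), empty
                    times, values = dm[obs]
                    return np.array([pos[t] for t in times], dtype=np.intp), values

                live_idx, live_y = index_of(LIVE_CELLS)
                pct_idx, pct_y = index_of(PCT_DIFFERENTIATED)
            else:
                dm_t, dm_s0 = empty, 0.0
                live_idx = pct_idx = np.empty(0, dtype=np.intp)
                live_y = pct_y = empty
            self._fast_blocks = (
                sr_t, sr_y, sr_s0, dm_t, dm_s0, live_idx, live_y, pct_idx, pct_y
            )
        return self._fast_blocks


def _predictions_for_block(theta: ParameterSet, dataset: KineticsDataset, medium, obs, times):
    init = dataset.initial_condition(medium)
    total, pct = _predict_arrays(theta.dynamic, init, times)
    return total if obs == LIVE_CELLS else pct


def _nll_raw(rho_S, delta_SC, rho_C, delta_CB, rho_B, b1, b2, fast_blocks) -> float:
    """-2 log L from raw parameter scalars; inf marks infeasible points."""
    from ._kernels import nll_kernel

    return nll_kernel(
        float(rho_S), float(delta_SC), float(rho_C), float(delta_CB),
        float(rho_B), float(b1), float(b2), *fast_blocks,
    )


def neg_log_likelihood(theta: ParameterSet, data: KineticsDataset) -> float:
    """-2 log L of the multiplicative-Gaussian error model (constant dropped).

    Returns ``+inf`` (infeasible point, recorded in the log) whenever a model
    prediction is non-positive at an observed timepoint, since the log term
    and the standard deviation are then undefined.
    """
    d, e = theta.dynamic, theta.error
    return _nll_raw(
        d.rho_S, d.delta_SC, d.rho_C, d.delta_CB, d.rho_B, e.b1, e.b2,
        data.fast_blocks(),
    )


@dataclass
class FitResult:
    """Outcome of a (multistart) maximum-likelihood fit."""

    theta_hat: ParameterSet
    neg2logL: float
    k: int
    n_obs: int
    converged: bool
    n_restarts_used: int
    seed: int | None

    def __post_init__(self):
        if not math.isfinite(self.neg2logL):
            raise InvalidParameterError("FitResult requires a finite -2 log L")


class KineticsMLE(BaseEstimator):
    """Bounded multistart maximum-likelihood estimator for the kinetics model.

    Parameters
    ----------
    free : sequence of str or bool, optional
        Which of the six estimable parameters (rho_S, rho_C, delta_CB,
        rho_B, b1, b2) to optimize.  Either a sequence of names or a
        6-vector of booleans in canonical order.  Default: all six.
    bounds : dict, optional
        Per-parameter (low, high) optimizer bounds; defaults to
        :data:`DEFAULT_BOUNDS`.
    n_restarts : int, default 50
        Number of uniform random initial guesses drawn within bounds.  The
        anchor itself is always tried first, so ``n_restarts + 1`` local
        searches are run.
    seed : int, default 0
        Seed for the restart draws; fits are bit-reproducible given the seed.
    epsilon, clearance_T : float
        Parameters of the delta_SC clearance constraint.
    gtol : float, default 1e-8
        Gradient tolerance passed to the truncated-Newton optimizer.
    max_iter : int, default 1000
        Iteration cap per local search.

    Attributes
    ----------
    theta_ : ParameterSet
        The maximum-likelihood estimate.
    result_ : FitResult
        Full fit record (-2 log L, parameter count, sample size, seed).
    """

    def __init__(
        self,
        free=None,
        bounds=None,
        n_restarts: int = 50,
        seed: int = 0,
        epsilon: float = DEFAULT_EPSILON,
        clearance_T: float = DEFAULT_CLEARANCE_T,
        gtol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.free = free
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.seed = seed
        self.epsilon = epsilon
        self.clearance_T = clearance_T
        self.gtol = gtol
        self.max_iter = max_iter

    # -- helpers -----------------------------------------------------------
    def _free_mask(self) -> np.ndarray:
        if self.free is None:
            return np.ones(6, dtype=bool)
        free = self.free
        if len(free) == 0:
            return np.zeros(6, dtype=bool)
        if all(isinstance(f, str) for f in free):
            unknown = set(free) - set(FREE_PARAMETER_NAMES)
            if unknown:
                raise InvalidParameterError(f"unknown parameter names: {sorted(unknown)}")
            return np.array([name in free for name in FREE_PARAMETER_NAMES])
        mask = np.asarray(list(free), dtype=bool)
        if mask.shape != (6,):
            raise InvalidParameterError("free mask must have exactly 6 entries")
        return mask

    def _bounds_array(self) -> np.ndarray:
        bounds = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds.update(self.bounds)
        return np.array([bounds[name] for name in FREE_PARAMETER_NAMES], dtype=float)

    def _rebuild(self, anchor_vec, mask, x):
        vec = anchor_vec.copy()
        vec[mask] = x
        return _build_parameter_set(vec, self.epsilon, self.clearance_T)

    # -- estimator API -----------------------------------------------------
    def fit(self, data: KineticsDataset, anchor: ParameterSet | None = None):
        """Fit the freed parameters to ``data``, tying the rest to ``anchor``."""
        if anchor is None:
            anchor = default_anchor(self.epsilon, self.clearance_T)
        mask = self._free_mask()
        bounds = self._bounds_array()
        anchor_vec = anchor.free_values()
        k = int(mask.sum())

        if k == 0:
            theta = _build_parameter_set(anchor_vec, self.epsilon, self.clearance_T)
            nll = neg_log_likelihood(theta, data)
            if not math.isfinite(nll):
                raise ConvergenceError("anchor parameters are infeasible for this data")
            self.theta_ = theta
            self.result_ = FitResult(theta, nll, 0, data.n_obs, True, 0, self.seed)
            return self

        # infeasible points (non-positive predictions) get a large finite
        # penalty instead of inf so finite-difference gradients stay defined
        PENALTY = 1e12
        blocks = data.fast_blocks()
        log_inv_eps = math.log(1.0 / self.epsilon)
        full = anchor_vec.copy()

        def objective(x):
            if not np.all(np.isfinite(x)):
                return PENALTY
            full[mask] = x
            rho_S, rho_C, delta_CB, rho_B, b1, b2 = full
            if delta_CB < 0 or b1 <= 0 or b2 <= 0:
                return PENALTY
            delta_SC = max(0.0, rho_S + log_inv_eps / self.clearance_T)
            val = _nll_raw(rho_S, delta_SC, rho_C, delta_CB, rho_B, b1, b2, blocks)
            return val if math.isfinite(val) else PENALTY

        rng = np.random.default_rng(self.seed)
        lo, hi = bounds[mask, 0], bounds[mask, 1]
        starts = [np.clip(anchor_vec[mask], lo, hi)]
        starts.extend(rng.uniform(lo, hi) for _ in range(self.n_restarts))

        best_x, best_val, best_ok, n_used = None, math.inf, False, 0
        for x0 in starts:
            if objective(x0) >= PENALTY:
                continue
            res = minimize(
                objective,
                x0,
                method="TNC",
                bounds=list(zip(lo, hi)),
                options={"gtol": self.gtol, "maxfun": self.max_iter * 10},
            )
            n_used += 1
            if math.isfinite(res.fun) and res.fun < min(best_val, PENALTY):
                best_x, best_val, best_ok = res.x, float(res.fun), bool(res.success)
        if best_x is None:
            raise ConvergenceError(
                f"no restart produced a finite -2 log L (tried {len(starts)})"
            )
        theta = self._rebuild(anchor_vec, mask, best_x)
        self.theta_ = theta
        self.result_ = FitResult(
            theta, best_val, k, data.n_obs, best_ok, n_used, self.seed
        )
        return self

    def predict(self, times, medium: str = DIFFERENTIATION, y0: float = 1.0):
        """Predicted (total live cells, percent differentiated) at ``times``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "theta_")
        init = InitialCondition(CompartmentState(y0, 0.0, 0.0, 0.0), medium)
        total, pct = _predict_arrays(self.theta_.dynamic, init, np.asarray(times, float))
        return np.column_stack([total, pct])

    def score(self, data: KineticsDataset) -> float:
        """Log-likelihood (up to constant): higher is better, sklearn-style."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "theta_")
        return -0.5 * neg_log_likelihood(self.theta_, data)


def _build_parameter_set(vec, epsilon, clearance_T):
    rho_S, rho_C, delta_CB, rho_B, b1, b2 = (float(v) for v in vec)
    dyn = DynamicParameters(
        rho_S=rho_S,
        delta_SC=fix_delta_SC(rho_S, epsilon, clearance_T, warn=False),
        rho_C=rho_C,
        delta_CB=delta_CB,
        rho_B=rho_B,
    )
    return ParameterSet(dynamic=dyn, error=ErrorParameters(b1, b2))


def fit(
    data: KineticsDataset,
    free=None,
    anchor: ParameterSet | None = None,
    **config,
) -> FitResult:
    """Functional wrapper around :class:`KineticsMLE`."""
    est = KineticsMLE(free=free, **config)
    est.fit(data, anchor=anchor)
    return est.result_


def profile_likelihood(
    data: KineticsDataset,
    free,
    anchor: ParameterSet | None,
    target_param: str,
    grid,
    **config,
) -> list[tuple[float, float]]:
    """Profile -2 log L over a grid of values of one freed parameter.

    For each grid value the target parameter is fixed and all other freed
    parameters are re-optimized; the resulting profile is everywhere >= the
    unconstrained minimum, with equality near the MLE.
    """
    if target_param not in FREE_PARAMETER_NAMES:
        raise InvalidParameterError(f"unknown parameter {target_param!r}")
    base = KineticsMLE(free=free, **config)
    mask = base._free_mask()
    idx = FREE_PARAMETER_NAMES.index(target_param)
    if not mask[idx]:
        raise InvalidParameterError(f"{target_param!r} is not among the freed parameters")
    if anchor is None:
        anchor = default_anchor()
    remaining = [
        n for i, n in enumerate(FREE_PARAMETER_NAMES) if mask[i] and i != idx
    ]
    profile = []
    for value in grid:
        if not math.isfinite(value):
            raise InvalidParameterError("profile grid must be finite")
        pinned_vec = anchor.free_values()
        pinned_vec[idx] = value
        pinned = _build_parameter_set(pinned_vec, base.epsilon, base.clearance_T)
        est = KineticsMLE(free=remaining, **config)
        est.fit(data, anchor=pinned)
        profile.append((float(value), est.result_.neg2logL))
    return profile
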