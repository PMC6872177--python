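"""AICc model selection over parameter-variation variants of the kinetics model.

Under a drug treatment, each of the six estimable parameters (rho_S, rho_C,
delta_CB, rho_B, b1, b2) can either be re-estimated from the treatment data
or tied to the value fitted on the control condition.  This defines
2^6 = 64 nested model variants per treatment.  Each variant is fitted by
maximum likelihood, scored with the small-sample corrected Akaike
information criterion ::

    AICc = -2 log L + 2 k n / (n - k - 1)

(k = number of treatment-stage estimated parameters, n = number of
treatment observations), converted to Akaike weights ::

    w_i = exp(-(AICc_i - min AICc)/2) / sum_j exp(-(AICc_j - min AICc)/2)

and the best variants are the shortest weight-sorted prefix whose
cumulative weight reaches a probability threshold (0.95 by default).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    InvalidParameterError,
    UndefinedCriterionError,
)
from .likelihood import (
    FREE_PARAMETER_NAMES,
    FitResult,
    KineticsDataset,
    KineticsMLE,
    ParameterSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelVariant",
    "ModelScore",
    "SelectionResult",
    "enumerate_variants",
    "aicc",
    "akaike_weights",
    "select_best",
    "run_treatment_selection",
    "TreatmentModelSelection",
]


@dataclass(frozen=True, order=True)
class ModelVariant:
    """One assignment of free-vs-tied for the six estimable parameters.

    ``free_flags[i]`` is True when the i-th parameter (canonical order
    rho_S, rho_C, delta_CB, rho_B, b1, b2) is estimated from the treatment
    data, False when it is tied to its control value.
    """

    free_flags: tuple[bool, bool, bool, bool, bool, bool]

    def __post_init__(self):
        if len(self.free_flags) != 6:
            raise InvalidParameterError("a variant has exactly 6 free/tied flags")

    @property
    def k(self) -> int:
        """Number of treatment-stage estimated parameters."""
        return sum(self.free_flags)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(
            n for n, f in zip(FREE_PARAMETER_NAMES, self.free_flags) if f
        )

    def label(self) -> str:
        return "+".join(self.free_names) if self.k else "control"


def enumerate_variants() -> list[ModelVariant]:
    """All 64 variants in lexicographic order over the canonical parameters."""
    return [
        ModelVariant(flags)
        for flags in itertools.product((False, True), repeat=6)
    ]


def aicc(neg2logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    Requires ``n > k + 1``; otherwise the correction denominator is
    non-positive and the criterion is undefined.
    """
    if n <= k + 1:
        raise UndefinedCriterionError(
            f"AICc undefined for n={n}, k={k} (need n > k + 1)"
        )
    return neg2logL + 2.0 * k * n / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: normalized relative evidence within a model set.

    Invariant under adding a constant to every AICc; weights sum to 1.
    Entries with infinite AICc (failed fits) get weight 0.
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise InvalidParameterError("empty AICc list")
    if np.any(np.isnan(a)):
        raise InvalidParameterError("AICc values must not be NaN")
    finite = np.isfinite(a)
    if not finite.any():
        raise InvalidParameterError("all AICc values are infinite")
    rel = a - a[finite].min()
    w = np.where(finite, np.exp(-0.5 * rel, where=finite, out=np.zeros_like(a)), 0.0)
    return w / w.sum()


@dataclass
class ModelScore:
    """A fitted variant with its AICc and Akaike weight."""

    variant: ModelVariant
    fit: FitResult | None
    aicc: float
    weight: float = float("nan")


@dataclass
class SelectionResult:
    """All scored variants (sorted by descending weight) and the selected prefix."""

    scored: list[ModelScore]
    selected: list[ModelScore]
    threshold: float

    def summary(self) -> pd.DataFrame:
        """One row per variant: flags, k, -2logL, AICc, weight, selected flag."""
        sel = {id(s) for s in self.selected}
        rows = []
        for s in self.scored:
            row = {
                name: flag
                for name, flag in zip(FREE_PARAMETER_NAMES, s.variant.free_flags)
            }
            row.update(
                k=s.variant.k,
                neg2logL=s.fit.neg2logL if s.fit is not None else math.inf,
                aicc=s.aicc,
                weight=s.weight,
                selected=id(s) in sel,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def select_best(scored: list[ModelScore], threshold: float = 0.95) -> SelectionResult:
    """Keep the shortest descending-weight prefix with cumulative weight >= threshold.

    Ties in weight are broken by variant lexicographic order so the result
    is deterministic.
    """
    if not (0 < threshold <= 1):
        raise InvalidParameterError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(scored, key=lambda s: (-s.weight, s.variant.free_flags))
    selected, cum = [], 0.0
    for s in ordered:
        if cum >= threshold:
            break
        if s.weight > 0:
            selected.append(s)
            cum += s.weight
    return SelectionResult(scored=ordered, selected=selected, threshold=threshold)


class TreatmentModelSelection(BaseEstimator):
    """Full control-vs-treatment model-selection pipeline.

    Fits the control dataset with all six parameters free, then fits all 64
    variants to the treatment dataset with tied parameters anchored to the
    control estimates, scores each with AICc, computes Akaike weights and
    selects the 95% cumulative-weight set.

    Parameters
    ----------
    threshold : float, default 0.95
        Cumulative Akaike-weight probability for the selected set.
    n_restarts_control : int, default 50
        Multistart restarts for the (six-parameter) control fit.
    n_restarts : int, default 10
        Multistart restarts per variant fit; the control anchor is always
        used as an additional starting point, which makes small counts
        effective for the nested variants.
    seed : int, default 0
        Base seed; each variant fit gets a distinct deterministic sub-seed.
    bounds, epsilon, clearance_T, gtol, max_iter :
        Passed through to :class:`erythropy.likelihood.KineticsMLE`.

    Attributes
    ----------
    control_fit_ : FitResult
        Control-stage maximum-likelihood fit.
    result_ : SelectionResult
        Scored and selected variants.
    summary_ : pandas.DataFrame
        Per-variant report (flags, k, -2logL, AICc, weight, selected).
    relative_parameters_ : pandas.DataFrame
        Selected models x 6 parameters, each fitted value divided by its
        control value (the treatment-effect display).
    """

    def __init__(
        self,
        threshold: float = 0.95,
        n_restarts_control: int = 50,
        n_restarts: int = 10,
        seed: int = 0,
        bounds=None,
        epsilon: float = 0.01,
        clearance_T: float = 48.0,
        gtol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.threshold = threshold
        self.n_restarts_control = n_restarts_control
        self.n_restarts = n_restarts
        self.seed = seed
        self.bounds = bounds
        self.epsilon = epsilon
        self.clearance_T = clearance_T
        self.gtol = gtol
        self.max_iter = max_iter

    def _mle(self, free, n_restarts, seed):
        return KineticsMLE(
            free=free,
            bounds=self.bounds,
            n_restarts=n_restarts,
            seed=seed,
            epsilon=self.epsilon,
            clearance_T=self.clearance_T,
            gtol=self.gtol,
            max_iter=self.max_iter,
        )

    def fit(
        self,
        control_data: KineticsDataset,
        treatment_data: KineticsDataset,
        control_anchor: ParameterSet | None = None,
    ):
        """Run the two-stage selection; see class docstring."""
        control_est = self._mle(None, self.n_restarts_control, self.seed)
        control_est.fit(control_data, anchor=control_anchor)
        self.control_fit_ = control_est.result_
        anchor = self.control_fit_.theta_hat

        scores: list[ModelScore] = []
        n = treatment_data.n_obs
        for j, variant in enumerate(enumerate_variants()):
            sub_seed = (self.seed * 1000 + j) % (2**31 - 1)
            try:
                est = self._mle(list(variant.free_flags), self.n_restarts, sub_seed)
                est.fit(treatment_data, anchor=anchor)
                fit_res = est.result_
                crit = aicc(fit_res.neg2logL, variant.k, n)
            except UndefinedCriterionError as err:
                warnings.warn(
                    f"variant {variant.label()} excluded: {err}", RuntimeWarning
                )
                scores.append(ModelScore(variant, None, math.inf))
                continue
            except ConvergenceError as err:
                warnings.warn(
                    f"variant {variant.label()} failed to converge: {err}",
                    RuntimeWarning,
                )
                scores.append(ModelScore(variant, None, math.inf))
                continue
            scores.append(ModelScore(variant, fit_res, crit))
            logger.info(
                "variant %s: k=%d -2logL=%.3f AICc=%.3f",
                variant.label(), variant.k, fit_res.neg2logL, crit,
            )

        weights = akaike_weights([s.aicc for s in scores])
        for s, w in zip(scores, weights):
            s.weight = float(w)
        self.result_ = select_best(scores, self.threshold)
        self.summary_ = self.result_.summary()
        self.relative_parameters_ = self._relative_parameters(anchor)
        return self

    def _relative_parameters(self, anchor: ParameterSet) -> pd.DataFrame:
        ref = anchor.free_values()
        rows = []
        for s in self.result_.selected:
            vals = s.fit.theta_hat.free_values()
            rows.append(
                dict(
                    zip(FREE_PARAMETER_NAMES, np.divide(vals, ref)),
                    variant=s.variant.label(),
                    weight=s.weight,
                )
            )
        return pd.DataFrame(rows)


def run_treatment_selection(
    control_data: KineticsDataset,
    treatment_data: KineticsDataset,
    **config,
) -> TreatmentModelSelection:
    """Functional wrapper around :class:`TreatmentModelSelection`."""
    return TreatmentModelSelection(**config).fit(control_data, treatment_data)
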