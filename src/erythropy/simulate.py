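"""Synthetic kinetics and single-cell expression data generators.

These simulators produce data with the statistical structure the analysis
assumes, so every pipeline stage can be exercised and calibrated without
the original measurements.

* Kinetics: observations are drawn from the generative reading of the
  multiplicative-Gaussian error model, ``y ~ Normal(f, b * f)`` around the
  exact compartment-model predictions, over the experimental design of the
  study (timepoints 0-96 h, 3 replicates, both media).
* Expression: per-gene lognormal single-cell distributions (continuous,
  heavy-tailed, as RT-qPCR expression levels are), with a treatment acting
  through a per-gene multiplier on the arithmetic mean and a per-gene
  multiplier on the log-scale dispersion sigma, plus a point mass at zero
  for limit-of-detection dropouts.  Parametrizing the mean directly (and
  solving for the lognormal location) keeps mean and dispersion effects
  orthogonal: a pure dispersion change leaves the mean untouched, which is
  exactly the "entropy changes without mean changes" pattern the analysis
  is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .entropy import ExpressionMatrix
from .kinetics import (
    DIFFERENTIATION,
    SELF_RENEWAL,
    DynamicParameters,
    fix_delta_SC,
)
from .likelihood import (
    LIVE_CELLS,
    PCT_DIFFERENTIATED,
    ErrorParameters,
    KineticsDataset,
    ParameterSet,
    _predictions_for_block,
)

__all__ = [
    "KineticsDesign",
    "ExpressionDesign",
    "simulate_kinetics",
    "simulate_expression",
    "make_treatment_scenario",
    "DEFAULT_TRUE_PARAMETERS",
]

#: Plausible fixture rates: ~23-35 h doubling times and 10% measurement noise.
DEFAULT_TRUE_PARAMETERS = ParameterSet(
    dynamic=DynamicParameters(
        rho_S=0.03,
        delta_SC=fix_delta_SC(0.03),
        rho_C=0.02,
        delta_CB=0.04,
        rho_B=0.01,
    ),
    error=ErrorParameters(0.1, 0.1),
)


@dataclass
class KineticsDesign:
    """Experimental design for a simulated kinetics dataset."""

    timepoints: tuple = (0.0, 12.0, 24.0, 48.0, 72.0, 96.0)
    replicates: int = 3
    media: tuple = (SELF_RENEWAL, DIFFERENTIATION)
    y0: dict = field(default_factory=lambda: {SELF_RENEWAL: 1e5, DIFFERENTIATION: 1e5})
    true_params: ParameterSet = field(default_factory=lambda: DEFAULT_TRUE_PARAMETERS)
    condition: str = "control"
    seed: int = 0
    clip_negative: bool = False

    def __post_init__(self):
        if 0.0 not in self.timepoints:
            raise InvalidParameterError("timepoints must include 0")
        if self.replicates < 1:
            raise InvalidParameterError("need at least one replicate")


def simulate_kinetics(design: KineticsDesign) -> KineticsDataset:
    """Draw a kinetics dataset from the error model around the exact solution.

    Each observation is an independent draw
    ``y ~ Normal(f_i(t), b_i * f_i(t))``; with ``b = 0`` the observations
    equal the model predictions exactly.  Reproducible given the seed.
    Negative draws are kept by default (faithful to the error model);
    ``clip_negative`` truncates them at 0.
    """
    rng = np.random.default_rng(design.seed)
    theta = design.true_params
    times = np.asarray(sorted(design.timepoints), dtype=float)
    rows = []
    # a stub dataset provides initial conditions for the predictor
    stub = _design_stub(design)
    for medium in design.media:
        observables = (
            (LIVE_CELLS,) if medium == SELF_RENEWAL else (LIVE_CELLS, PCT_DIFFERENTIATED)
        )
        for obs in observables:
            # the differentiated fraction is exactly 0 at induction (t = 0),
            # where the multiplicative error model is undefined; it is only
            # observed at later timepoints
            obs_times = times[times > 0] if obs == PCT_DIFFERENTIATED else times
            f = _predictions_for_block(theta, stub, medium, obs, obs_times)
            if np.any(f <= 0):
                raise InvalidParameterError(
                    f"design yields non-positive predictions for {medium}/{obs}"
                )
            b = theta.error.b1 if obs == LIVE_CELLS else theta.error.b2
            for t, mean in zip(obs_times, f):
                draws = rng.normal(mean, b * mean, size=design.replicates)
                if design.clip_negative:
                    draws = np.clip(draws, 0.0, None)
                if obs == PCT_DIFFERENTIATED:
                    draws = np.clip(draws, 0.0, 100.0)
                for k, y in enumerate(draws, start=1):
                    rows.append(
                        dict(
                            condition=design.condition,
                            medium=medium,
                            time_h=t,
                            replicate=k,
                            observable=obs,
                            value=float(y),
                        )
                    )
    return KineticsDataset(
        data=pd.DataFrame(rows), y0=dict(design.y0), condition=design.condition
    )


def _design_stub(design: KineticsDesign) -> KineticsDataset:
    df = pd.DataFrame(
        dict(
            condition=[design.condition],
            medium=[DIFFERENTIATION],
            time_h=[0.0],
            replicate=[1],
            observable=[LIVE_CELLS],
            value=[design.y0.get(DIFFERENTIATION, 1.0)],
        )
    )
    return KineticsDataset(data=df, y0=dict(design.y0), condition=design.condition)


@dataclass
class ExpressionDesign:
    """Generative design for paired control/treated expression matrices.

    Control expression of gene g is lognormal with log-location ``mu[g]``
    and log-scale ``sigma[g] > 0``.  The treatment multiplies the gene's
    arithmetic mean by ``mean_effect[g]`` and its sigma by
    ``dispersion_effect[g]``; a ``dropout`` fraction of entries is set to 0
    (limit of detection).  Scalars broadcast over genes; per-gene arrays are
    accepted.  Default baseline parameters are drawn once from the seed:
    log-locations uniform over [0, ln 100] and sigmas uniform over
    [0.25, 0.6].  The sigma range keeps the linear-scale histogram entropy
    monotone in the dispersion (for larger sigma the lognormal piles most
    mass into the lowest bins and entropy turns over), while every gene
    remains positively skewed / heavy-tailed.
    """

    n_genes: int = 92
    n_cells: int = 60
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    mean_effect: float | np.ndarray = 1.0
    dispersion_effect: float | np.ndarray = 1.0
    dropout: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise InvalidParameterError(f"dropout must be in [0, 1), got {self.dropout}")
        if np.any(np.asarray(self.mean_effect) <= 0) or np.any(
            np.asarray(self.dispersion_effect) <= 0
        ):
            raise InvalidParameterError("effect multipliers must be > 0")


def simulate_expression(
    design: ExpressionDesign,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate a (control, treated) pair of expression matrices.

    The treated lognormal keeps ``mean_treated = mean_effect * mean_control``
    exactly by adjusting the log-location for the new sigma.  Reproducible
    given the seed.
    """
    rng = np.random.default_rng(design.seed)
    G, n = design.n_genes, design.n_cells
    mu = (
        np.asarray(design.mu, dtype=float)
        if design.mu is not None
        else rng.uniform(0.0, np.log(100.0), size=G)
    )
    sigma = (
        np.asarray(design.sigma, dtype=float)
        if design.sigma is not None
        else rng.uniform(0.25, 0.6, size=G)
    )
    if mu.shape != (G,) or sigma.shape != (G,):
        raise InvalidParameterError("mu and sigma must have one entry per gene")
    if np.any(sigma <= 0):
        raise InvalidParameterError("sigma must be > 0")
    m = np.broadcast_to(np.asarray(design.mean_effect, dtype=float), (G,))
    s = np.broadcast_to(np.asarray(design.dispersion_effect, dtype=float), (G,))

    sigma_t = sigma * s
    # hold the arithmetic mean: exp(mu' + sigma_t^2/2) = m * exp(mu + sigma^2/2)
    mu_t = mu + np.log(m) + 0.5 * (sigma**2 - sigma_t**2)

    genes = [f"gene_{i + 1:03d}" for i in range(G)]
    control = rng.lognormal(mu[:, None], sigma[:, None], size=(G, n))
    treated = rng.lognormal(mu_t[:, None], sigma_t[:, None], size=(G, n))
    for arr in (control, treated):
        mask = rng.random(arr.shape) < design.dropout
        arr[mask] = 0.0
    cols_c = [f"cell_{i + 1:03d}" for i in range(n)]
    return (
        ExpressionMatrix(pd.DataFrame(control, index=genes, columns=cols_c), "control"),
        ExpressionMatrix(pd.DataFrame(treated, index=genes, columns=cols_c), "treated"),
    )


_SCENARIOS = {
    # treated multipliers on (rho_C, delta_CB, rho_B) relative to control
    "null": (1.0, 1.0, 1.0),
    "noise_down": (0.6, 0.5, 1.0),  # slower commitment/exit: Indo/Arte-like
    "noise_up": (1.5, 1.8, 0.7),  # faster transit, slower B growth: MB-3-like
}


def make_treatment_scenario(name: str) -> tuple[ParameterSet, ParameterSet]:
    """Paired (control, treated) parameter sets for end-to-end tests.

    ``noise_down`` reduces the differentiation rate delta_CB (and rho_C), as
    drugs that reduce expression variability slow differentiation;
    ``noise_up`` increases them while lowering rho_B; ``null`` leaves the
    parameters unchanged.
    """
    if name not in _SCENARIOS:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        )
    mc, md, mb = _SCENARIOS[name]
    control = DEFAULT_TRUE_PARAMETERS
    d = control.dynamic
    treated = ParameterSet(
        dynamic=DynamicParameters(
            rho_S=d.rho_S,
            delta_SC=d.delta_SC,
            rho_C=d.rho_C * mc,
            delta_CB=d.delta_CB * md,
            rho_B=d.rho_B * mb,
        ),
        error=control.error,
    )
    return control, treated
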