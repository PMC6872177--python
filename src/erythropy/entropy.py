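"""Histogram Shannon entropy of single-cell gene expression and comparisons.

Cell-to-cell variability of each gene is quantified by the Shannon entropy
of a basic histogram of its single-cell expression levels: with ``Nc``
cells and ``N = Nc / 2`` equal-width bins, the probabilities ``p_k`` are
bin counts divided by ``Nc`` and ::

    E = - sum_k p_k log2(p_k)     (0 * log 0 = 0)

so E = 0 when every cell expresses the same amount and E = log2(N) for the
most variable (uniform) pattern.  ``Nc`` is held fixed across all compared
groups: larger groups are subsampled (seeded) and bin edges are pooled over
the two compared conditions, so treated/control entropies share a support
and their ratio is meaningful.

A drug's effect is summarized per gene by the relative entropy
RE = E_treated / E_control, ordered descending; genes strictly above the
upper quartile of the RE distribution are the most positively affected,
genes strictly below the lower quartile the most negatively affected.
Shifts are tested with a paired Wilcoxon signed-rank test over genes;
agreement between drugs and entropy-vs-mean relations use Pearson
correlation; differentiation time courses are compared per timepoint with
a two-sample Student t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "ExpressionMatrix",
    "EntropyTable",
    "RelativeEntropyTable",
    "gene_entropy",
    "entropy_table",
    "paired_entropy_tables",
    "relative_entropy",
    "quartile_classify",
    "entropy_shift_test",
    "CorrelationResult",
    "drug_pair_correlation",
    "entropy_mean_correlation",
    "differentiation_timecourse_test",
    "EntropyComparison",
]


@dataclass
class ExpressionMatrix:
    """Gene x cell expression levels for one condition and timepoint.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    cell; entries are continuous, non-negative expression levels (zeros mark
    limit-of-detection values and are kept as numbers).
    """

    values: pd.DataFrame
    condition: str = "control"
    timepoint: float = 0.0

    def __post_init__(self):
        if self.values.isna().any().any():
            raise InvalidInputError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise InvalidInputError("expression levels must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class EntropyTable:
    """Per-gene Shannon entropies (bits) with the histogram geometry used."""

    entropies: pd.Series
    n_bins: int
    n_cells: int


@dataclass
class RelativeEntropyTable:
    """Per-gene treated/control entropy ratios with quartile labels.

    ``table`` has columns ``RE`` (descending) and ``quartile`` in
    {"upper", "middle", "lower"}; genes with undefined ratio (control
    entropy 0 while treated > 0) are listed in ``undefined``.
    """

    table: pd.DataFrame
    undefined: list[str]


def gene_entropy(values, Nc: int, range: tuple[float, float]) -> float:
    """Histogram Shannon entropy (bits) of one gene's expression levels.

    Builds ``N = Nc / 2`` equal-width bins over ``range`` (rightmost bin
    closed), converts counts to probabilities and returns
    ``-sum p_k log2 p_k``.  The result lies in [0, log2 N].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty expression vector")
    if Nc < 2 or Nc % 2 != 0:
        raise InvalidParameterError(f"Nc must be an even integer >= 2, got {Nc}")
    lo, hi = range
    if hi < lo:
        raise InvalidParameterError(f"invalid range ({lo}, {hi})")
    if np.any(v < lo) or np.any(v > hi):
        raise InvalidInputError(
            "values outside the histogram range; pass the pooled range"
        )
    n_bins = Nc // 2
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def _pick_nc(n_cells_groups, Nc=None) -> int:
    nc = min(n_cells_groups) if Nc is None else Nc
    nc = int(nc)
    if nc % 2:
        nc -= 1
    if nc < 2:
        raise InvalidInputError("need at least 2 cells per group for the histogram")
    return nc


def entropy_table(
    matrix: ExpressionMatrix,
    Nc: int | None = None,
    ranges: pd.DataFrame | None = None,
    seed: int | None = 0,
) -> EntropyTable:
    """Per-gene entropies of one expression matrix with a fixed cell count.

    ``Nc`` defaults to the matrix's own (even-floored) cell count; larger
    matrices are subsampled to exactly ``Nc`` cells with the given seed so
    histograms over different groups are comparable.  ``ranges`` optionally
    provides per-gene (lo, hi) bin supports (e.g. pooled over the compared
    conditions); by default each gene uses its own observed range.
    """
    nc = _pick_nc([matrix.n_cells], Nc)
    if nc > matrix.n_cells:
        raise InvalidInputError(
            f"Nc={nc} exceeds the {matrix.n_cells} cells available"
        )
    vals = matrix.values
    if nc < matrix.n_cells:
        if seed is None:
            raise InvalidParameterError("subsampling to Nc requires a seed")
        rng = np.random.default_rng(seed)
        cols = rng.choice(matrix.n_cells, size=nc, replace=False)
        vals = vals.iloc[:, np.sort(cols)]
    ent = {}
    for gene, row in vals.iterrows():
        v = row.to_numpy(dtype=float)
        if ranges is not None:
            lo, hi = ranges.loc[gene, "lo"], ranges.loc[gene, "hi"]
        else:
            lo, hi = float(v.min()), float(v.max())
        ent[gene] = gene_entropy(v, nc, (lo, hi))
    return EntropyTable(pd.Series(ent, name="entropy"), n_bins=nc // 2, n_cells=nc)


def _pooled_ranges(*matrices: ExpressionMatrix) -> pd.DataFrame:
    genes = matrices[0].genes
    for m in matrices[1:]:
        if list(m.genes) != list(genes):
            raise InvalidInputError("matrices must share an identical gene set")
    lo = np.min([m.values.min(axis=1).to_numpy() for m in matrices], axis=0)
    hi = np.max([m.values.max(axis=1).to_numpy() for m in matrices], axis=0)
    return pd.DataFrame({"lo": lo, "hi": hi}, index=genes)


def paired_entropy_tables(
    control: ExpressionMatrix,
    treated: ExpressionMatrix,
    Nc: int | None = None,
    seed: int = 0,
) -> tuple[EntropyTable, EntropyTable]:
    """Entropy tables for two conditions under one shared histogram geometry.

    ``Nc`` defaults to the smaller group's cell count (floored to even); the
    larger group is subsampled, and per-gene bin ranges are pooled over both
    conditions so the two tables are directly comparable.
    """
    nc = _pick_nc([control.n_cells, treated.n_cells], Nc)
    ranges = _pooled_ranges(control, treated)
    ec = entropy_table(control, nc, ranges, seed=seed)
    et = entropy_table(treated, nc, ranges, seed=seed + 1)
    return ec, et


def relative_entropy(
    treated: EntropyTable, control: EntropyTable
) -> RelativeEntropyTable:
    """Per-gene RE = E_treated / E_control, descending, with quartile labels.

    Genes whose control entropy is 0 while the treated entropy is positive
    have an undefined ratio; they are reported separately and excluded from
    the quartile classification.  Genes with both entropies 0 get RE = 1
    (no change).
    """
    ec, et = control.entropies, treated.entropies
    if not ec.index.equals(et.index):
        raise InvalidInputError("entropy tables must share the same gene set")
    undefined = list(ec.index[(ec == 0) & (et > 0)])
    keep = ~ec.index.isin(undefined)
    with np.errstate(invalid="ignore"):
        re = (et[keep] / ec[keep]).fillna(1.0)  # 0/0 -> unchanged
    re = re.sort_values(ascending=False)
    table = pd.DataFrame({"RE": re})
    table["quartile"] = quartile_classify(re)
    return RelativeEntropyTable(table=table, undefined=undefined)


def quartile_classify(re_values: pd.Series) -> pd.Series:
    """Label genes by where their RE falls in the RE distribution.

    With values sorted descending, the upper cut q1 is the 75th percentile
    and the lower cut q3 the 25th (linear-interpolation percentiles).
    Genes strictly above q1 are "upper" (most positively affected by the
    drug), strictly below q3 "lower", the rest "middle".
    """
    re_values = pd.Series(re_values)
    if re_values.size < 4:
        raise InvalidInputError("quartile classification needs at least 4 genes")
    q1 = float(np.percentile(re_values, 75))
    q3 = float(np.percentile(re_values, 25))
    labels = np.where(
        re_values > q1, "upper", np.where(re_values < q3, "lower", "middle")
    )
    return pd.Series(labels, index=re_values.index, name="quartile")


def entropy_shift_test(treated_entropies, control_entropies) -> float:
    """Paired two-sided Wilcoxon signed-rank test on per-gene entropies.

    Exact p-value for 25 or fewer informative pairs (no zero differences),
    normal approximation with continuity correction otherwise.  Returns 1.0
    when every difference is zero (degenerate test).
    """
    t = np.asarray(treated_entropies, dtype=float)
    c = np.asarray(control_entropies, dtype=float)
    if t.shape != c.shape:
        raise InvalidInputError("paired entropy vectors must have equal length")
    d = t - c
    if np.all(d == 0):
        return 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if (n_nonzero <= 25 and not np.any(d == 0)) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(t, c, alternative="two-sided", method=method,
                             correction=(method == "approx"))
    return float(res.pvalue)


@dataclass
class CorrelationResult:
    """Pearson correlation with the fitted line (reported when significant)."""

    r: float
    p: float
    slope: float
    intercept: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _pearson_with_line(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InvalidInputError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        # degenerate: no variation on one axis, correlation undefined
        return CorrelationResult(r=0.0, p=1.0, slope=0.0, intercept=float(np.mean(y)))
    lin = stats.linregress(x, y)
    return CorrelationResult(
        r=float(lin.rvalue), p=float(lin.pvalue),
        slope=float(lin.slope), intercept=float(lin.intercept),
    )


def drug_pair_correlation(
    re_A: RelativeEntropyTable | pd.Series, re_B: RelativeEntropyTable | pd.Series
) -> CorrelationResult:
    """Pearson correlation of per-gene relative entropies between two drugs."""
    a = re_A.table["RE"] if isinstance(re_A, RelativeEntropyTable) else pd.Series(re_A)
    b = re_B.table["RE"] if isinstance(re_B, RelativeEntropyTable) else pd.Series(re_B)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise InvalidInputError("fewer than 3 genes in common")
    return _pearson_with_line(a[common], b[common])


def entropy_mean_correlation(
    re_table: RelativeEntropyTable | pd.Series, relative_means: pd.Series
) -> CorrelationResult:
    """Pearson correlation of relative entropy vs relative mean expression."""
    re = (
        re_table.table["RE"]
        if isinstance(re_table, RelativeEntropyTable)
        else pd.Series(re_table)
    )
    rm = pd.Series(relative_means)
    common = re.index.intersection(rm.index)
    if len(common) < 3:
        raise InvalidInputError("fewer than 3 genes in common")
    return _pearson_with_line(rm[common], re[common])


def differentiation_timecourse_test(
    treated: pd.DataFrame, control: pd.DataFrame
) -> pd.Series:
    """Per-timepoint two-sample Student t-test on percent differentiated.

    Both inputs are tables with columns (time_h, value), one row per
    replicate.  Returns a Series of two-sided p-values indexed by timepoint.
    When both groups have zero variance the test is degenerate: p = 1.0 for
    equal means, 0.0 otherwise, with a warning.
    """
    out = {}
    times = sorted(set(treated["time_h"]) & set(control["time_h"]))
    for t in times:
        a = treated.loc[treated["time_h"] == t, "value"].to_numpy(dtype=float)
        b = control.loc[control["time_h"] == t, "value"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise InvalidInputError(f"need >= 2 replicates per group at t={t}")
        if np.var(a) == 0 and np.var(b) == 0:
            warnings.warn(
                f"zero variance in both groups at t={t}; degenerate t-test",
                RuntimeWarning,
            )
            out[t] = 1.0 if np.mean(a) == np.mean(b) else 0.0
            continue
        res = stats.ttest_ind(a, b, equal_var=True)
        out[t] = float(res.pvalue)
    return pd.Series(out, name="p_value")


class EntropyComparison(BaseEstimator):
    """Treated-vs-control entropy analysis for one drug at one timepoint.

    Computes paired entropy tables (shared Nc and pooled per-gene bin
    ranges), the relative-entropy table with quartile labels, per-gene
    relative mean expression, the Wilcoxon entropy-shift p-value and the
    entropy-vs-mean Pearson correlation.

    Parameters
    ----------
    Nc : int, optional
        Number of cells entering each histogram (N = Nc/2 bins).  Default:
        the smaller group's cell count, floored to an even number.
    seed : int, default 0
        Seed for subsampling larger groups down to Nc cells.

    Attributes
    ----------
    control_entropies_, treated_entropies_ : EntropyTable
    relative_ : RelativeEntropyTable
    relative_means_ : pandas.Series
    shift_p_ : float
    mean_correlation_ : CorrelationResult
    """

    def __init__(self, Nc: int | None = None, seed: int = 0):
        self.Nc = Nc
        self.seed = seed

    def fit(self, control: ExpressionMatrix, treated: ExpressionMatrix):
        ec, et = paired_entropy_tables(control, treated, self.Nc, self.seed)
        self.control_entropies_ = ec
        self.treated_entropies_ = et
        self.relative_ = relative_entropy(et, ec)
        mc = control.values.mean(axis=1)
        mt = treated.values.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.relative_means_ = (mt / mc).replace([np.inf, -np.inf], np.nan)
        self.shift_p_ = entropy_shift_test(
            et.entropies.to_numpy(), ec.entropies.to_numpy()
        )
        self.mean_correlation_ = entropy_mean_correlation(
            self.relative_, self.relative_means_.dropna()
        )
        return self

    def transform(self, *_args) -> pd.DataFrame:
        """The relative-entropy table (RE, quartile) as a DataFrame."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "relative_")
        return self.relative_.table
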