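"""Histogram entropy estimator, relative entropy, and the comparative statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import erythropy as e
from erythropy.exceptions import InvalidInputError, InvalidParameterError


def brute_force_entropy(values, n_bins, lo, hi):
    """Two-pass counting oracle, independent of numpy.histogram."""
    values = list(values)
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in values:
        idx = n_bins - 1 if v == hi else int((v - lo) / width)
        idx = min(idx, n_bins - 1)
        counts[idx] += 1
    total = len(values)
    ent = 0.0
    for c in counts:
        if c:
            p = c / total
            ent -= p * np.log2(p)
    return ent


class TestGeneEntropy:
    def test_constant_input_has_null_entropy(self):
        assert e.gene_entropy([5.0] * 10, 10, (0, 10)) == 0.0

    def test_uniform_fill_reaches_log2_n(self):
        vals = [0.1, 0.2, 1.1, 1.2, 2.1, 2.2, 3.1, 3.2]  # 4 bins, 2 each
        assert e.gene_entropy(vals, 8, (0, 4)) == pytest.approx(2.0)

    def test_hand_computed_histogram(self):
        # counts (2, 3, 1) over 3 bins of [0, 3]
        expected = -(2 / 6 * np.log2(2 / 6) + 3 / 6 * np.log2(3 / 6) + 1 / 6 * np.log2(1 / 6))
        assert e.gene_entropy([0, 0, 1, 1, 1, 3], 6, (0, 3)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            nc = 2 * rng.integers(1, 40)
            vals = rng.lognormal(1.0, 1.0, size=rng.integers(2, 80))
            lo, hi = 0.0, float(vals.max())
            assert e.gene_entropy(vals, int(nc), (lo, hi)) == pytest.approx(
                brute_force_entropy(vals, int(nc) // 2, lo, hi), abs=1e-12
            )

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=60),
        st.integers(min_value=1, max_value=30),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounds_and_permutation_invariance(self, values, half_nc):
        nc = 2 * half_nc
        lo, hi = min(values), max(values)
        ent = e.gene_entropy(values, nc, (lo, hi))
        assert 0.0 <= ent <= np.log2(max(nc // 2, 2)) + 1e-12
        ent_perm = e.gene_entropy(list(reversed(values)), nc, (lo, hi))
        assert ent == pytest.approx(ent_perm, abs=1e-12)

    def test_odd_nc_rejected(self):
        with pytest.raises(InvalidParameterError):
            e.gene_entropy([1, 2], 3, (0, 3))

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            e.gene_entropy([1, 5], 4, (0, 3))


def matrix_from_array(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"c{i}" for i in range(arr.shape[1])]
    return e.ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cols))


class TestEntropyTable:
    def test_constant_matrix_all_zero(self):
        m = matrix_from_array(np.full((5, 12), 3.0))
        table = e.entropy_table(m)
        assert (table.entropies == 0).all()
        assert table.n_bins == 6

    def test_bimodal_gene_exceeds_constant_gene(self):
        rng = np.random.default_rng(0)
        constant = np.full(40, 5.0)
        bimodal = np.concatenate([rng.normal(1, 0.1, 20), rng.normal(9, 0.1, 20)])
        m = matrix_from_array(np.vstack([constant, bimodal]), ["flat", "bimodal"])
        t = e.entropy_table(m)
        assert t.entropies["bimodal"] > t.entropies["flat"]

    def test_dispersion_increase_raises_entropy(self):
        """Doubling the log-scale dispersion raises entropy in >= 95% of seeds."""
        wins = 0
        n_trials = 200
        for s in range(n_trials):
            rng = np.random.default_rng(s)
            narrow = rng.lognormal(2.0, 0.6, 60)
            wide = rng.lognormal(2.0, 1.2, 60)
            lo, hi = 0.0, float(max(narrow.max(), wide.max()))
            wins += e.gene_entropy(wide, 60, (lo, hi)) > e.gene_entropy(
                narrow, 60, (lo, hi)
            )
        assert wins / n_trials >= 0.95

    def test_subsampling_requires_seed_and_is_deterministic(self):
        rng = np.random.default_rng(1)
        m = matrix_from_array(rng.lognormal(1, 1, (4, 50)))
        t1 = e.entropy_table(m, Nc=30, seed=5)
        t2 = e.entropy_table(m, Nc=30, seed=5)
        assert (t1.entropies == t2.entropies).all()
        with pytest.raises(InvalidParameterError):
            e.entropy_table(m, Nc=30, seed=None)

    def test_paired_tables_share_geometry(self):
        rng = np.random.default_rng(2)
        c = matrix_from_array(rng.lognormal(1, 1, (6, 50)))
        t = matrix_from_array(rng.lognormal(1, 1.5, (6, 44)))
        ec, et = e.paired_entropy_tables(c, t, seed=0)
        assert ec.n_cells == et.n_cells == 44
        assert ec.n_bins == et.n_bins == 22


class TestRelativeEntropy:
    def test_identical_tables_give_unit_ratios(self):
        ent = pd.Series([1.0, 2.0, 0.5, 1.5], index=list("abcd"))
        t = e.EntropyTable(ent, 4, 8)
        re = e.relative_entropy(t, t)
        assert (re.table["RE"] == 1.0).all()

    def test_simple_ratio(self):
        c = e.EntropyTable(pd.Series({"a": 1.0, "b": 2.0, "c": 1.0, "d": 1.0}), 4, 8)
        t = e.EntropyTable(pd.Series({"a": 2.0, "b": 1.0, "c": 1.0, "d": 3.0}), 4, 8)
        re = e.relative_entropy(t, c)
        assert re.table.loc["a", "RE"] == pytest.approx(2.0)
        # ordered descending as in the report
        assert list(re.table["RE"]) == sorted(re.table["RE"], reverse=True)

    def test_undefined_ratio_reported_and_excluded(self):
        c = e.EntropyTable(pd.Series({"a": 0.0, "b": 1.0, "c": 1.0, "d": 1.0, "x": 2.0}), 4, 8)
        t = e.EntropyTable(pd.Series({"a": 1.0, "b": 1.0, "c": 2.0, "d": 0.5, "x": 2.0}), 4, 8)
        re = e.relative_entropy(t, c)
        assert re.undefined == ["a"]
        assert "a" not in re.table.index

    def test_both_zero_counts_as_unchanged(self):
        c = e.EntropyTable(pd.Series({"a": 0.0, "b": 1.0, "c": 1.0, "d": 2.0}), 4, 8)
        t = e.EntropyTable(pd.Series({"a": 0.0, "b": 1.0, "c": 2.0, "d": 1.0}), 4, 8)
        re = e.relative_entropy(t, c)
        assert re.table.loc["a", "RE"] == 1.0


class TestQuartileClassify:
    def test_linear_interpolation_example(self):
        re = pd.Series([1, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefgh"), dtype=float)
        labels = e.quartile_classify(re)
        assert set(re.index[labels == "upper"]) == {"g", "h"}  # strictly > 6.25
        assert set(re.index[labels == "lower"]) == {"a", "b"}  # strictly < 2.75
        assert (labels.isin(["upper", "middle", "lower"])).all()

    def test_degenerate_distribution_all_middle(self):
        labels = e.quartile_classify(pd.Series([1.0] * 6))
        assert (labels == "middle").all()

    def test_single_outlier_alone_in_upper(self):
        re = pd.Series([1.0, 1.0, 1.0, 1.0, 1.0, 10.0], index=list("abcdef"))
        labels = e.quartile_classify(re)
        assert list(re.index[labels == "upper"]) == ["f"]

    def test_too_few_genes(self):
        with pytest.raises(InvalidInputError):
            e.quartile_classify(pd.Series([1.0, 2.0, 3.0]))


class TestShiftAndCorrelationTests:
    def test_identical_entropies_give_p_one(self):
        x = np.linspace(0.5, 3, 50)
        assert e.entropy_shift_test(x, x) == 1.0

    def test_uniform_shift_is_significant(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(1, 3, 50)
        assert e.entropy_shift_test(c + 0.5, c) < 0.05

    def test_small_sample_uses_exact_distribution(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(1, 3, 12)
        p = e.entropy_shift_test(c + rng.normal(0, 0.05, 12), c)
        assert 0 < p <= 1

    def test_perfect_correlation(self):
        x = pd.Series(np.arange(10, dtype=float), index=[f"g{i}" for i in range(10)])
        res = e.drug_pair_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(1.0)

    def test_hand_computed_five_gene_correlation(self):
        idx = list("abcde")
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=idx)
        y = pd.Series([2.0, 1.0, 4.0, 3.0, 5.0], index=idx)
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        res = e.drug_pair_correlation(x, y)
        assert res.r == pytest.approx(float(r_hand), rel=1e-12)

    def test_permuted_values_uncorrelated(self):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.uniform(0.5, 2, 92), index=[f"g{i}" for i in range(92)])
        y = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
        res = e.drug_pair_correlation(x, y)
        assert abs(res.r) < 0.3

    def test_constant_axis_reported_not_significant(self):
        re = pd.Series([1.0, 1.2, 0.8, 1.4], index=list("abcd"))
        means = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        res = e.entropy_mean_correlation(re, means)
        assert not res.significant and res.r == 0.0

    def test_too_few_common_genes(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(InvalidInputError):
            e.drug_pair_correlation(x, x)

    def test_entropy_mean_inverse_correlation_recovered(self):
        """A drug lowering mean log-expression while widening its dispersion
        yields a negative entropy-vs-mean correlation across genes.

        Simulated on the log scale (Gaussian log-expression), where a mean
        change translates the histogram instead of rescaling its support, so
        entropy responds to the dispersion component alone.
        """
        signs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            G, n = 92, 60
            u = rng.random(G)  # per-gene drug susceptibility
            base_mean = rng.uniform(3.0, 8.0, G)
            base_sd = rng.uniform(0.5, 1.0, G)
            c_vals = np.clip(
                rng.normal(base_mean[:, None], base_sd[:, None], (G, n)), 0, None
            )
            t_vals = np.clip(
                rng.normal(
                    (base_mean * (1 - 0.35 * u))[:, None],
                    (base_sd * (1 + 1.5 * u))[:, None],
                    (G, n),
                ),
                0,
                None,
            )
            c = matrix_from_array(c_vals)
            t = matrix_from_array(t_vals)
            cmp_ = e.EntropyComparison(seed=s).fit(c, t)
            signs.append(cmp_.mean_correlation_.r)
        assert np.median(signs) < 0


class TestTimecourseTest:
    @staticmethod
    def course(values_by_time):
        rows = [
            {"time_h": t, "value": v} for t, vals in values_by_time.items() for v in vals
        ]
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one(self):
        g = self.course({24.0: [10.0, 12.0, 14.0], 48.0: [30.0, 32.0, 31.0]})
        p = e.differentiation_timecourse_test(g, g.copy())
        assert np.allclose(p.to_numpy(), 1.0)

    def test_separated_groups_significant(self):
        a = self.course({24.0: [10.0, 10.1, 9.9]})
        b = self.course({24.0: [20.0, 20.1, 19.9]})
        assert e.differentiation_timecourse_test(a, b)[24.0] < 0.05

    def test_degenerate_zero_variance_warns(self):
        a = self.course({24.0: [10.0, 10.0]})
        b = self.course({24.0: [10.0, 10.0]})
        with pytest.warns(RuntimeWarning):
            p = e.differentiation_timecourse_test(a, b)
        assert p[24.0] == 1.0

    def test_single_replicate_rejected(self):
        a = self.course({24.0: [10.0]})
        b = self.course({24.0: [10.0, 11.0]})
        with pytest.raises(InvalidInputError):
            e.differentiation_timecourse_test(a, b)

    def test_null_calibration_with_three_replicates(self):
        """Type-I error of the t-test at alpha = 0.05 with n = 3 per group."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            a = self.course({24.0: rng.normal(50, 5, 3).tolist()})
            b = self.course({24.0: rng.normal(50, 5, 3).tolist()})
            rejections += e.differentiation_timecourse_test(a, b)[24.0] < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09
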