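"""Expression preprocessing, signatures, HOX grouping and DE."""

import numpy as np
import pandas as pd
import pytest

from pamlcat import (
    ExpressionMatrix,
    SignatureSet,
    differential_expression,
    filter_expressed,
    hox_group_assign,
    log2cpm,
    outlier_expression_flag,
    select_variable_genes,
    signature_score,
)


def matrix(values, genes=None, samples=None, units="raw_counts"):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), units=units
    )


class TestFilterExpressed:
    def test_boundary_five_samples_kept_four_dropped(self):
        # library size exactly 1e5 per sample -> count 1 = 10 cpm exactly
        counts = np.zeros((3, 8))
        counts[0, :5] = 1  # 10 cpm in exactly 5 samples
        counts[1, :4] = 1  # only 4 samples
        counts[2, :] = 100000 - counts[:2].sum(axis=0)
        m = matrix(counts, genes=["keep", "drop", "filler"])
        out = filter_expressed(m)
        assert "keep" in out.genes and "drop" not in out.genes

    def test_all_zero_gene_dropped(self):
        counts = np.vstack([np.zeros((1, 6)), np.full((1, 6), 1000)])
        out = filter_expressed(matrix(counts, genes=["zero", "expr"]))
        assert out.genes == ["expr"]


class TestLog2Cpm:
    def test_count_8_in_million_reads(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 8
        counts[1, 0] = 1e6 - 8
        out = log2cpm(matrix(counts))
        assert out.data.iloc[0, 0] == pytest.approx(3.0)

    def test_low_cpm_floored_to_zero_and_zero_count_zero(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 0.5 * 2  # cpm 0.5 given 2e6 library
        counts[1, 0] = 2e6 - 1
        out = log2cpm(matrix(counts))
        assert out.data.iloc[0, 0] == 0.0
        zero = np.vstack([[0.0], [100.0]])
        assert log2cpm(matrix(zero)).data.iloc[0, 0] == 0.0

    def test_output_nonnegative_and_units_tagged(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.poisson(5, (20, 10)) + 1)
        out = log2cpm(m)
        assert out.units == "log2cpm"
        assert (out.data.to_numpy() >= 0).all()

    def test_zero_library_names_sample(self):
        counts = np.zeros((2, 2))
        counts[:, 0] = 5
        with pytest.raises(ValueError, match="S1"):
            log2cpm(matrix(counts))


class TestVariableGenes:
    def test_planted_high_variance_block_recovered(self):
        rng = np.random.default_rng(1)
        quiet = rng.normal(5, 0.01, (30, 20))
        loud = rng.normal(5, 3.0, (5, 20))
        genes = [f"Q{i}" for i in range(30)] + [f"LOUD{i}" for i in range(5)]
        m = matrix(np.vstack([quiet, loud]), genes=genes, units="log2cpm")
        sig = select_variable_genes(m, n=5)
        assert sig.genes == frozenset(f"LOUD{i}" for i in range(5))

    def test_n_equal_gene_count_returns_all(self):
        m = matrix(np.random.default_rng(2).normal(size=(7, 5)), units="log2cpm")
        assert len(select_variable_genes(m, n=7).genes) == 7

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 8))
        m = matrix(vals, units="log2cpm")
        shuffled = ExpressionMatrix(
            data=m.data[list(reversed(m.samples))], units="log2cpm"
        )
        assert select_variable_genes(m, 4).genes == select_variable_genes(shuffled, 4).genes


class TestSignatureScore:
    def test_case_at_cohort_mean_scores_zero(self):
        # probe sample S4 sits exactly at the per-gene cohort mean
        vals = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 2.5]), (3, 1))
        m = matrix(vals, genes=["A", "B", "C"], units="log2cpm")
        assert signature_score(m, SignatureSet("s", frozenset("ABC")), "S4") == 0.0

    def test_case_two_sd_above_mean_scores_two(self):
        # values [-1, 1, -1, 1, x] on every signature gene: solve for the
        # probe value x whose z-score (including the probe itself) is 2
        from scipy.optimize import brentq

        sym = np.array([-1.0, 1.0] * 6)

        def probe_z(x):
            v = np.r_[sym, x]
            return (x - v.mean()) / v.std()

        x = brentq(lambda t: probe_z(t) - 2.0, 0.1, 50.0)
        vals = np.tile(np.r_[sym, x], (3, 1))
        m = matrix(vals, genes=["A", "B", "C"], units="log2cpm")
        score = signature_score(m, SignatureSet("s", frozenset("ABC")), "S12")
        assert score == pytest.approx(2.0, abs=1e-9)

    def test_missing_overlap_is_error(self):
        m = matrix(np.ones((2, 3)), genes=["A", "B"], units="log2cpm")
        with pytest.raises(ValueError):
            signature_score(m, SignatureSet("s", frozenset(["ZZZ"])), "S0")


class TestHoxGrouping:
    def _scores_matrix(self):
        """Three archetypes: HOXA-only high, both high, both low."""
        rng = np.random.default_rng(4)
        n_each = 12
        hoxa_genes = ["HOXA9", "HOXA10", "MEIS1"]
        hoxb_genes = ["HOXB2", "HOXB3", "HOXB4", "HOXB5"]
        cols = {}
        for i in range(n_each):
            cols[f"A{i}"] = dict.fromkeys(hoxa_genes, 10.0) | dict.fromkeys(hoxb_genes, 0.0)
            cols[f"B{i}"] = dict.fromkeys(hoxa_genes, 10.0) | dict.fromkeys(hoxb_genes, 10.0)
            cols[f"O{i}"] = dict.fromkeys(hoxa_genes, 0.0) | dict.fromkeys(hoxb_genes, 0.0)
        df = pd.DataFrame(cols) + rng.normal(0, 0.05, (7, 3 * n_each))
        return ExpressionMatrix(data=df, units="log2cpm")

    def test_archetypes_assigned_to_expected_groups(self):
        groups = hox_group_assign(self._scores_matrix())
        assert (groups[groups.index.str.startswith("A")] == "HOXA").all()
        assert (groups[groups.index.str.startswith("B")] == "HOXB").all()
        assert (groups[groups.index.str.startswith("O")] == "other").all()

    def test_synthetic_cohort_recovery_at_least_95_percent(self, default_synthetic):
        cohort, expr, markers, truth = default_synthetic
        groups = hox_group_assign(log2cpm(expr))
        agree = np.mean(
            [groups[c] == truth.loc[c, "hox_group"] for c in truth.index]
        )
        assert agree >= 0.95


class TestOutlierFlag:
    def test_planted_overexpression_flags(self, default_synthetic):
        cohort, expr, markers, truth = default_synthetic
        m = log2cpm(expr)
        mecom_cases = truth.index[truth.category == "MECOM"]
        assert len(mecom_cases) > 0
        flagged = [outlier_expression_flag(m, "MECOM", c) for c in mecom_cases]
        assert all(flagged)

    def test_case_at_mean_not_flagged(self):
        vals = np.tile(np.linspace(1, 3, 9), (2, 1))
        m = matrix(vals, genes=["MECOM", "X"], units="log2cpm")
        assert not outlier_expression_flag(m, "MECOM", "S4")

    def test_zero_variance_gene_warns_false(self):
        m = matrix(np.ones((1, 5)), genes=["MECOM"], units="log2cpm")
        with pytest.warns(UserWarning):
            assert outlier_expression_flag(m, "MECOM", "S0") is False


class TestDifferentialExpression:
    def _planted(self, fold=4.0, n=20, noise=0.1, seed=5):
        rng = np.random.default_rng(seed)
        base = rng.normal(6, noise, (30, 2 * n))
        base[0, :n] += np.log2(fold)  # planted up-regulated gene
        genes = ["PLANTED"] + [f"G{i}" for i in range(29)]
        samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        m = ExpressionMatrix(
            data=pd.DataFrame(base, index=genes, columns=samples),
            units="log2cpm",
        )
        return m, samples[:n], samples[n:]

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(6)
        vals = np.tile(rng.normal(5, 1, (10, 1)), (1, 8))
        m = matrix(vals, units="log2cpm")
        out = differential_expression(m, m.samples[:4], m.samples[4:])
        assert not out["significant"].any()

    def test_planted_fourfold_gene_flagged(self):
        m, a, b = self._planted()
        out = differential_expression(m, a, b)
        assert out.loc["PLANTED", "significant"]
        assert out.loc["PLANTED", "fold_change"] == pytest.approx(4.0, rel=0.15)
        assert not out.drop("PLANTED")["significant"].any()

    def test_permuted_labels_fdr_controlled(self):
        m, a, b = self._planted()
        rng = np.random.default_rng(7)
        mixed = rng.permutation(a + b)
        out = differential_expression(m, list(mixed[:20]), list(mixed[20:]))
        assert out["significant"].sum() <= 1

    def test_overlapping_groups_error(self):
        m, a, b = self._planted()
        with pytest.raises(ValueError):
            differential_expression(m, a, a)
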