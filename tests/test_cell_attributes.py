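import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import permtyper as pt

from conftest import make_norm


def gini_oracle(y):
    """Mean-absolute-difference form: G = sum_ij |y_i - y_j| / (2 n^2 ybar)."""
    y = np.asarray(y, dtype=float)
    return np.abs(y[:, None] - y[None, :]).sum() / (2 * len(y) ** 2 * y.mean())


positive_vectors = st.lists(
    st.floats(min_value=1e-3, max_value=1e3, allow_nan=False), min_size=1,
    max_size=200)


class TestGini:
    def test_closed_forms(self):
        assert pt.gini_index([3.0, 3.0, 3.0]) == pytest.approx(0.0, abs=1e-15)
        assert pt.gini_index([0, 0, 0, 8]) == pytest.approx(0.75)
        assert pt.gini_index([1, 2, 3, 4]) == pytest.approx(0.25)

    def test_matches_mean_absolute_difference_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            y = rng.lognormal(0, 1, rng.integers(1, 300))
            assert pt.gini_index(y) == pytest.approx(gini_oracle(y), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(positive_vectors, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, y, c):
        assert pt.gini_index(np.array(y) * c) == pytest.approx(
            pt.gini_index(y), abs=1e-9)

    def test_transfer_to_richer_value_increases_inequality(self):
        rng = np.random.default_rng(1)
        y = np.sort(rng.lognormal(0, 1, 50))
        richer = y.copy()
        delta = y[0] / 2
        richer[0] -= delta
        richer[-1] += delta
        assert pt.gini_index(richer) > pt.gini_index(y)

    def test_empty_and_negative(self):
        assert np.isnan(pt.gini_index([]))
        with pytest.raises(ValueError):
            pt.gini_index([-1.0, 2.0])


class TestChromFractions:
    def test_forced_percentages(self):
        counts = np.array([5, 20, 0, 75])
        cls = np.array(["MT", "X", "Y", "AUTO"], dtype=object)
        mt, x, y = pt.chrom_fractions(counts, cls)
        assert (mt, x, y) == (5.0, 20.0, 0.0)

    def test_missing_class_yields_zero_and_fractions_conserve(self):
        counts = np.array([10, 90])
        cls = np.array(["MT", "AUTO"], dtype=object)
        mt, x, y = pt.chrom_fractions(counts, cls)
        assert x == 0.0 and y == 0.0
        auto = 100.0 * 90 / 100
        assert mt + x + y + auto == 100.0

    def test_zero_total_undefined(self):
        out = pt.chrom_fractions(np.zeros(3), np.array(["MT", "X", "AUTO"],
                                                       dtype=object))
        assert all(np.isnan(v) for v in out)


class TestDiversity:
    def test_identical_cells_have_zero_diversity(self):
        X = np.tile(np.array([1.0, 2.0, 3.0, 0.5]), (2, 1))
        np.testing.assert_allclose(pt.diversity(X), [0.0, 0.0], atol=1e-12)

    def test_anticorrelated_pair_reaches_two(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        np.testing.assert_allclose(pt.diversity(X), [2.0, 2.0], atol=1e-12)

    def test_iid_noise_diversity_near_one(self):
        rng = np.random.default_rng(0)
        n_genes = 400
        means = []
        for _ in range(20):
            X = rng.normal(size=(10, n_genes))
            means.append(np.nanmean(pt.diversity(X)))
        # E[r] ~ 0 for independent profiles; SE of each pairwise r ~ 1/sqrt(G)
        se = 1 / np.sqrt(n_genes) / np.sqrt(len(means))
        assert abs(np.mean(means) - 1.0) < 4 * se

    def test_singleton_type_undefined(self):
        assert np.isnan(pt.diversity(np.ones((1, 5)))[0])

    def test_zero_variance_cell_excluded_with_warning(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = pt.diversity(X)
        assert np.isnan(d[0])
        np.testing.assert_allclose(d[1:], [2.0, 2.0], atol=1e-12)

    def test_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 50))
        Y = X * rng.uniform(0.5, 2, size=(6, 1)) + rng.normal(size=(6, 1))
        np.testing.assert_allclose(pt.diversity(X), pt.diversity(Y), atol=1e-9)


class TestAttributeTable:
    def test_micro_fixture_values(self, micro):
        m, expected = micro
        filt, _ = pt.filter_cells_genes(m, 1, 0)
        norm = pt.normalize(filt)
        attrs = pt.compute_attributes(filt, norm)
        f1 = attrs.iloc[0]
        assert f1["chrM_pct"] == expected["f1_chrM_pct"]
        assert f1["chrX_pct"] == expected["f1_chrX_pct"]
        assert f1["chrY_pct"] == expected["f1_chrY_pct"]
        assert f1["umi_log10"] == pytest.approx(np.log10(40))
        assert f1["n_genes"] == 8

    def test_diversity_column_per_label(self, micro):
        m, _ = micro
        filt, _ = pt.filter_cells_genes(m, 1, 0)
        norm = pt.normalize(filt)
        labels = np.array(["A", "A", "A", "B", "B", "C"], dtype=object)
        attrs = pt.compute_attributes(filt, norm, labels)
        assert np.isnan(attrs["diversity"].iloc[5])  # singleton type C
        assert attrs["diversity"].iloc[:5].notna().all()


class TestAttributeGeneCorrelation:
    def test_exact_negative_linear_relation(self):
        rng = np.random.default_rng(0)
        expr = rng.uniform(1, 5, size=100)
        norm = make_norm(np.c_[expr, rng.uniform(size=100)])
        attrs = pd.DataFrame({"fake": 10 - 2 * expr})
        rep = pt.attribute_gene_correlation(norm, attrs, "g0", "fake")
        assert rep.loc[0, "pcc"] == pytest.approx(-1.0)

    def test_independent_attribute_uncorrelated(self):
        rng = np.random.default_rng(1)
        expr = rng.uniform(1, 5, size=1000)
        norm = make_norm(expr[:, None])
        attrs = pd.DataFrame({"fake": rng.permutation(expr)})
        rep = pt.attribute_gene_correlation(norm, attrs, "g0", "fake")
        assert abs(rep.loc[0, "pcc"]) < 0.1

    def test_planted_repressor_recovers_negative_sign(self):
        """A gene coupled to reduced transcriptome breadth correlates
        negatively with the expressed-gene count in expressing cells."""
        import dataclasses
        base = pt.default_config(seed=0, doublet_rate=0.0)
        cfg = dataclasses.replace(base,
                                  attribute_coupling=pt.AttributeCoupling())
        signs = []
        for seed in range(5):
            mat, truth = pt.generate(dataclasses.replace(cfg, seed=seed))
            filt, _ = pt.filter_cells_genes(mat)
            norm = pt.normalize(filt)
            attrs = pt.compute_attributes(filt, norm)
            rep = pt.attribute_gene_correlation(norm, attrs, "Repressor1",
                                                "n_genes")
            signs.append(rep.loc[0, "pcc"] < 0)
        assert np.mean(signs) >= 0.95

    def test_sparse_stratum_skipped_with_warning(self):
        expr = np.array([2.0, 3.0, 0.0, 0.0, 1.0, 2.5])
        norm = make_norm(expr[:, None])
        attrs = pd.DataFrame({"gini": np.linspace(0, 1, 6)})
        labels = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        with pytest.warns(UserWarning, match="skipped"):
            rep = pt.attribute_gene_correlation(norm, attrs, "g0", "gini",
                                                labels)
        assert set(rep["stratum"]) == {"pooled"}

    def test_constant_attribute_undefined(self):
        expr = np.arange(1.0, 11.0)
        norm = make_norm(expr[:, None])
        attrs = pd.DataFrame({"gini": np.ones(10)})
        rep = pt.attribute_gene_correlation(norm, attrs, "g0", "gini")
        assert np.isnan(rep.loc[0, "pcc"])
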