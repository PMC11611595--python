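"""Statistical engine: bootstrap t, BH, KS, Bray-Curtis, PERMANOVA, PCA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from nexudate.stats import (
    bh_adjust,
    bootstrap_t_test,
    bray_curtis_binary,
    ks_two_sample,
    pca_squared_cosines,
    permanova,
)


# ------------------------------------------------------------ bootstrap test

class TestBootstrapT:
    def test_null_case_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = bootstrap_t_test(x, x, n_boot=2000, seed=0)
        assert res.p_value > 0.9

    def test_power_on_separated_groups(self, rng):
        x = rng.normal(0, 1, 5)
        y = rng.normal(3, 1, 5)
        res = bootstrap_t_test(x, y, n_boot=2000, seed=1)
        assert res.p_value < 0.05

    def test_deterministic_given_seed(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        r1 = bootstrap_t_test(x, y, n_boot=500, seed=7)
        r2 = bootstrap_t_test(x, y, n_boot=500, seed=7)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    def test_p_never_zero(self, rng):
        res = bootstrap_t_test(rng.normal(0, 1, 5), rng.normal(50, 1, 5),
                               n_boot=500, seed=0)
        assert 0 < res.p_value <= 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bootstrap_t_test([1.0, 2.0], [1.0, 2.0], n_boot=10)


# ---------------------------------------------------------------- BH adjust

class TestBHAdjust:
    def test_hand_computed_stepup(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([]).size == 0

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(10):
            p = rng.uniform(0, 1, size=rng.integers(2, 30))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected)

    def test_order_preserving(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_range_validation(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ------------------------------------------------------------------------ KS

class TestKS:
    def test_identical_and_disjoint(self):
        x = np.arange(10.0)
        assert ks_two_sample(x, x).statistic == 0.0
        assert ks_two_sample(x, x + 100).statistic == 1.0

    def test_statistic_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(5, 40))
            y = rng.normal(0.3, 1.2, rng.integers(5, 40))
            ours = ks_two_sample(x, y, mode="asymptotic")
            ref = scipy.stats.ks_2samp(x, y, method="asymp")
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_exact_p_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 7)
            y = rng.normal(0.5, 1, 9)
            ours = ks_two_sample(x, y, mode="exact")
            ref = scipy.stats.ks_2samp(x, y, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_p_reasonable(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        res = ks_two_sample(x, y, mode="asymptotic")
        ref = scipy.stats.ks_2samp(x, y, method="asymp")
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.02)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


# ---------------------------------------------------------------- Bray-Curtis

class TestBrayCurtis:
    def test_closed_form_counts(self):
        # A=3, B=5, J=2 -> (3+5-4)/8 = 0.5
        a = [1, 1, 1, 0, 0, 0, 0, 0]
        b = [1, 1, 0, 1, 1, 1, 0, 0]
        m = pd.DataFrame({"sa": a, "sb": b})
        d = bray_curtis_binary(m)
        assert d.loc["sa", "sb"] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        m = pd.DataFrame({"a": [1, 1, 0], "b": [1, 1, 0], "c": [0, 0, 1]})
        d = bray_curtis_binary(m)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_matches_scipy_pdist(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(30, 12)),
                         columns=[f"s{i}" for i in range(12)])
        ours = bray_curtis_binary(m).to_numpy()
        ref = squareform(pdist(m.to_numpy().T, metric="braycurtis"))
        assert np.allclose(ours, ref)

    def test_symmetry_range_and_diagonal(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(20, 8)))
        d = bray_curtis_binary(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_binary_enforced(self):
        with pytest.raises(ValueError):
            bray_curtis_binary(pd.DataFrame({"a": [2, 1], "b": [0, 1]}))


# ------------------------------------------------------------------ PERMANOVA

def _univariate_design(values, groups):
    ids = [f"s{i}" for i in range(len(values))]
    dist = pd.DataFrame(np.abs(np.subtract.outer(values, values)),
                        index=ids, columns=ids)
    design = pd.DataFrame({"sample_id": ids, "treatment": groups})
    return dist, design


class TestPermanova:
    def test_pseudo_f_equals_anova_f_on_univariate_euclidean(self, rng):
        """On Euclidean distances of one variable, pseudo-F is classical F."""
        for _ in range(5):
            values = rng.normal(0, 1, 12)
            groups = ["a"] * 6 + ["b"] * 6
            dist, design = _univariate_design(values, groups)
            res = permanova(dist, design, terms=("treatment",), n_perm=99, seed=0)
            f_perm = res.loc[res["term"] == "treatment", "F"].iloc[0]
            f_ref = scipy.stats.f_oneway(values[:6], values[6:]).statistic
            assert f_perm == pytest.approx(f_ref, rel=1e-9)

    def test_degrees_of_freedom_layout(self, rng):
        values = rng.normal(0, 1, 10)
        dist, design = _univariate_design(values, ["a"] * 5 + ["b"] * 5)
        res = permanova(dist, design, terms=("treatment",), n_perm=99, seed=0)
        table = res.set_index("term")["df"]
        assert table["treatment"] == 1
        assert table["Residual"] == 8
        assert table["Total"] == 9

    def test_r2_sums_to_one(self, rng):
        n = 20
        X = rng.integers(0, 2, size=(40, n))
        dist = pd.DataFrame(squareform(pdist(X.T, "braycurtis")),
                            index=[f"s{i}" for i in range(n)],
                            columns=[f"s{i}" for i in range(n)])
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "treatment": (["a", "b"] * 10),
            "day": np.repeat([0, 1, 2, 3], 5),
        })
        res = permanova(dist, design, terms=("treatment", "day", "treatment:day"),
                        n_perm=49, seed=3)
        body = res[res["term"] != "Total"]
        assert body["R2"].sum() == pytest.approx(1.0)
        assert body["SS"].sum() == pytest.approx(
            res.loc[res["term"] == "Total", "SS"].iloc[0])

    def test_matches_skbio_single_factor(self, rng):
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova
        n = 14
        X = rng.integers(0, 2, size=(30, n)).astype(float)
        d = squareform(pdist(X.T, "braycurtis"))
        ids = [f"s{i}" for i in range(n)]
        groups = ["a"] * 7 + ["b"] * 7
        ours = permanova(pd.DataFrame(d, index=ids, columns=ids),
                         pd.DataFrame({"sample_id": ids, "treatment": groups}),
                         terms=("treatment",), n_perm=99, seed=0)
        ref = sk_permanova(DistanceMatrix(d, ids), list(groups), permutations=99)
        f_ours = ours.loc[ours["term"] == "treatment", "F"].iloc[0]
        assert f_ours == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_permutation_p_in_open_interval(self, rng):
        values = rng.normal(0, 1, 10)
        dist, design = _univariate_design(values, ["a"] * 5 + ["b"] * 5)
        res = permanova(dist, design, terms=("treatment",), n_perm=99, seed=1)
        p = res.loc[res["term"] == "treatment", "p_value"].iloc[0]
        assert 0 < p <= 1

    def test_deterministic(self, rng):
        values = rng.normal(0, 1, 10)
        dist, design = _univariate_design(values, ["a"] * 5 + ["b"] * 5)
        r1 = permanova(dist, design, terms=("treatment",), n_perm=199, seed=5)
        r2 = permanova(dist, design, terms=("treatment",), n_perm=199, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_level_factor_rejected(self, rng):
        values = rng.normal(0, 1, 6)
        dist, design = _univariate_design(values, ["a"] * 6)
        with pytest.raises(ValueError, match="treatment"):
            permanova(dist, design, terms=("treatment",))

    def test_aliased_term_rejected(self, rng):
        values = rng.normal(0, 1, 8)
        ids = [f"s{i}" for i in range(8)]
        dist = pd.DataFrame(np.abs(np.subtract.outer(values, values)),
                            index=ids, columns=ids)
        design = pd.DataFrame({"sample_id": ids,
                               "treatment": ["a"] * 4 + ["b"] * 4,
                               "day": ["x"] * 4 + ["y"] * 4})  # aliased
        with pytest.raises(ValueError, match="day"):
            permanova(dist, design, terms=("treatment", "day"))


# ------------------------------------------------------------------------ PCA

class TestPCA:
    def test_rank_one_two_correlated_variables(self, rng):
        v = rng.normal(0, 1, 30)
        table = pd.DataFrame({"x": v, "y": 2 * v + 1})
        res = pca_squared_cosines(table)
        assert res.explained_variance[0] == pytest.approx(1.0)
        assert res.squared_cosines.loc["x", "PC1"] == pytest.approx(1.0)
        assert res.squared_cosines.loc["y", "PC1"] == pytest.approx(1.0)

    def test_squared_cosines_sum_to_one_per_variable(self, rng):
        table = pd.DataFrame(rng.dirichlet(np.ones(5), size=24),
                             columns=["CHON", "CHON-S", "CHON-P", "CHON-SP", "nonN"])
        supp = pd.DataFrame({"treatment": ["c", "d"] * 12,
                             "phase": np.repeat(["baseline", "treatment", "recovery"], 8)})
        res = pca_squared_cosines(table, supplementary=supp)
        sums = res.squared_cosines.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        # supplementary variables are present in the cosine table
        assert any(str(i).startswith("treatment=") for i in res.squared_cosines.index)

    def test_explained_variance_against_eigvals(self, rng):
        X = rng.normal(0, 1, size=(40, 4)) @ rng.normal(0, 1, size=(4, 4))
        table = pd.DataFrame(X, columns=list("abcd"))
        res = pca_squared_cosines(table)
        Z = (X - X.mean(0)) / X.std(0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z.T, bias=True)))[::-1]
        assert np.allclose(res.explained_variance, eig / eig.sum(), atol=1e-9)
        assert (np.diff(res.explained_variance) <= 1e-12).all()
        assert res.explained_variance.sum() == pytest.approx(1.0)

    def test_zero_variance_variable_dropped(self, rng):
        table = pd.DataFrame({"a": rng.normal(0, 1, 10),
                              "b": rng.normal(0, 1, 10),
                              "c": np.ones(10)})
        res = pca_squared_cosines(table)
        assert res.dropped == ["c"]
        assert "c" not in res.loadings.index

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            pca_squared_cosines(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            pca_squared_cosines(pd.DataFrame({"a": [1.0, 1.0, 1.0],
                                              "b": [2.0, 2.0, 2.0]}))
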