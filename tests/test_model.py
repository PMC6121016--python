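import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dectp.model import (
    benjamini_hochberg,
    beta_covariance,
    build_design_matrix,
    estimate_group_variances,
    fit_gene,
    run_dectp,
    shrink_variances,
    wald_test,
)
from conftest import brute_force_bh, brute_force_normal_equations


class TestDesignMatrix:
    def test_layout(self):
        d = build_design_matrix(3, [0.5, 0.8, 0.3])
        assert d.W.shape == (6, 2)
        np.testing.assert_array_equal(d.W[:, 0], 1.0)
        np.testing.assert_array_equal(d.W[:3, 1], 0.0)
        np.testing.assert_array_equal(d.W[3:, 1], [0.5, 0.8, 0.3])
        assert d.df == 4

    def test_purity_one_gives_group_indicator(self):
        d = build_design_matrix(4, [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(d.W[4:, 1], 1.0)

    @pytest.mark.parametrize("bad", [1.2, 0.0, -0.1])
    def test_out_of_range_purity_rejected(self, bad):
        with pytest.raises(ValueError, match="purities"):
            build_design_matrix(3, [0.5, 0.5, bad])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_design_matrix(2, [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="at least 3"):
            build_design_matrix(3, [0.5, 0.5])


class TestFitGene:
    def test_exact_fit_with_full_purity(self):
        # X=(0,2), lambda=(1,1), Y'=(3,5): two-group means, beta=(1,3).
        # (validation minima relaxed by padding each group to 3 identical-fit
        # samples is unnecessary: build W directly)
        W = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], float)
        z = np.array([0.0, 2.0, 3.0, 5.0])
        beta = brute_force_normal_equations(z, W)
        np.testing.assert_allclose(beta, [1.0, 3.0], atol=1e-12)

    def test_exact_mixture_recovery(self):
        # X=(0,0,0), lambda=(0.5,1.0,0.75), Y'=2*lambda: beta=(0,2) exactly
        d = build_design_matrix(3, [0.5, 1.0, 0.75])
        z = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 1.5])
        beta, resid = fit_gene(z, d)
        np.testing.assert_allclose(beta, [0.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_all_zero_expression(self):
        d = build_design_matrix(3, [0.4, 0.6, 0.8])
        beta, resid = fit_gene(np.zeros(6), d)
        np.testing.assert_array_equal(beta, 0.0)
        np.testing.assert_array_equal(resid, 0.0)

    def test_matches_normal_equation_oracle_on_random_instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            n0, n1 = rng.integers(3, 11, size=2)
            lam = rng.uniform(0.05, 0.95, size=n1)
            d = build_design_matrix(int(n0), lam)
            z = rng.normal(size=n0 + n1)
            beta, resid = fit_gene(z, d)
            np.testing.assert_allclose(
                beta, brute_force_normal_equations(z, d.W), atol=1e-10
            )
            # residuals orthogonal to the design
            np.testing.assert_allclose(d.W.T @ resid, 0.0, atol=1e-9)


class TestGroupVariances:
    def test_zero_residuals(self):
        assert estimate_group_variances(np.zeros(6), 3, 3) == (0.0, 0.0)

    def test_n_minus_2_denominators(self):
        resid = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        s2n, s2t = estimate_group_variances(resid, 3, 3)
        assert s2n == pytest.approx(2.0)  # 2 / (3-2)
        assert s2t == pytest.approx(2.0)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError, match="exceed 2"):
            estimate_group_variances(np.zeros(4), 2, 2)


class TestShrinkage:
    def test_identity_at_weight_zero(self):
        v = np.array([0.5, 2.0, 7.0])
        np.testing.assert_array_equal(shrink_variances(v, 0.0), v)

    def test_full_shrinkage_hits_geometric_mean(self):
        out = shrink_variances(np.array([1.0, 4.0]), 1.0)
        np.testing.assert_allclose(out, [2.0, 2.0])  # sqrt(1*4)

    def test_equal_variances_are_fixed_points(self):
        v = np.full(5, 3.7)
        for w in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(shrink_variances(v, w), v)

    def test_zero_variances_floored_before_log(self):
        out = shrink_variances(np.array([0.0, 1.0, 1.0]), 0.5)
        assert np.all(out > 0)

    @given(st.floats(0.01, 1.0), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_shrinkage_contracts_log_spread(self, w, seed):
        v = np.random.default_rng(seed).uniform(0.1, 10.0, size=20)
        out = shrink_variances(v, w)
        assert np.log(out).std() <= np.log(v).std() + 1e-12


class TestBetaCovariance:
    def test_purity_one_closed_form(self):
        d = build_design_matrix(4, np.ones(5))
        s2n, s2t = 2.0, 3.0
        cov = beta_covariance(d, s2n, s2t)
        assert cov[1, 1] == pytest.approx(s2n / 4 + s2t / 5, abs=1e-12)
        assert cov[0, 1] == pytest.approx(cov[1, 0], abs=1e-12)

    def test_zero_variances_give_zero_matrix(self):
        d = build_design_matrix(3, [0.3, 0.6, 0.9])
        np.testing.assert_array_equal(beta_covariance(d, 0.0, 0.0), 0.0)

    def test_homoscedastic_collapse_to_wtw_inverse(self):
        d = build_design_matrix(5, [0.2, 0.5, 0.7, 0.9])
        s = 1.7
        cov = beta_covariance(d, s, s)
        np.testing.assert_allclose(cov, s * np.linalg.inv(d.W.T @ d.W), atol=1e-10)

    def test_positive_semidefinite_and_symmetric(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n0, n1 = rng.integers(3, 8, size=2)
            d = build_design_matrix(int(n0), rng.uniform(0.05, 0.95, size=n1))
            cov = beta_covariance(d, rng.uniform(0, 3), rng.uniform(0, 3))
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)


class TestWaldTest:
    def test_zero_effect(self):
        t, p = wald_test([5.0, 0.0], np.eye(2), 10)
        assert (t, p) == (0.0, pytest.approx(1.0))

    def test_arithmetic(self):
        t, _ = wald_test([0.0, 3.0], np.array([[1, 0], [0, 2.25]]), 10)
        assert t == pytest.approx(2.0)

    def test_full_pipeline_worked_example(self, worked_example):
        d = build_design_matrix(
            worked_example["n_normal"], worked_example["purities"]
        )
        beta, resid = fit_gene(worked_example["z"], d)
        s2n, s2t = estimate_group_variances(resid, d.n_normal, d.n_tumor)
        cov = beta_covariance(d, s2n, s2t)
        t, p = wald_test(beta, cov, d.df)
        assert t == pytest.approx(worked_example["t"], abs=1e-10)
        assert d.df == 4

    def test_degenerate_zero_variance_zero_effect(self):
        t, p = wald_test([1.0, 0.0], np.zeros((2, 2)), 10)
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_zero_variance_nonzero_effect_warns(self):
        with pytest.warns(RuntimeWarning, match="zero effect variance"):
            t, p = wald_test([1.0, 2.0], np.zeros((2, 2)), 10)
        assert p == 0.0 and t == np.inf

    def test_monotone_in_effect_size(self):
        cov = np.array([[1.0, 0.0], [0.0, 0.5]])
        ts = [abs(wald_test([0.0, b], cov, 20)[0]) for b in (0.1, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(ts) > 0)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40), st.integers(0, 99))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_and_order_invariant(self, p, seed):
        p = np.asarray(p)
        np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)
        perm = np.random.default_rng(seed).permutation(len(p))
        np.testing.assert_allclose(
            benjamini_hochberg(p[perm]), brute_force_bh(p)[perm], atol=1e-12
        )


class TestRunDectp:
    def make_frame(self, z, n0):
        genes = ["g1"]
        cols = [f"n{i}" for i in range(n0)] + [f"t{i}" for i in range(len(z) - n0)]
        return pd.DataFrame([z], index=genes, columns=cols)

    def groups_for(self, df):
        return pd.Series(
            ["normal" if c.startswith("n") else "tumor" for c in df.columns],
            index=df.columns,
        )

    def test_single_gene_matches_hand_pipeline(self, worked_example):
        df = self.make_frame(worked_example["z"], 3)
        purity = pd.Series(1.0, index=["t0", "t1", "t2"])
        out = run_dectp(df, self.groups_for(df), purity, shrink_weight=0.0)
        assert out.loc["g1", "wald_t"] == pytest.approx(worked_example["t"], abs=1e-10)
        # p frozen from the t_4 survival-function oracle: 2*sf(2.598076, 4)
        assert out.loc["g1", "p_value"] == pytest.approx(0.06016985, rel=1e-5)

    def test_constant_genes_are_fully_null(self):
        df = pd.DataFrame(
            np.full((3, 6), 7.0),
            index=["a", "b", "c"],
            columns=["n0", "n1", "n2", "t0", "t1", "t2"],
        )
        purity = pd.Series([0.5, 0.7, 0.9], index=["t0", "t1", "t2"])
        out = run_dectp(df, self.groups_for(df), purity)
        np.testing.assert_array_equal(out["p_value"], 1.0)
        np.testing.assert_array_equal(out["wald_t"], 0.0)

    def test_gene_order_preserved_and_rank_is_permutation(self, small_dataset):
        ds = small_dataset
        out = run_dectp(ds.expression, ds.groups, ds.true_purities)
        assert list(out.index) == list(ds.expression.index)
        assert sorted(out["rank"]) == list(range(1, len(out) + 1))
        # permuting gene rows permutes the output rows identically
        perm = np.random.default_rng(0).permutation(len(ds.expression))
        shuffled = ds.expression.iloc[perm]
        out2 = run_dectp(shuffled, ds.groups, ds.true_purities)
        pd.testing.assert_frame_equal(
            out2.drop(columns="rank"), out.drop(columns="rank").iloc[perm]
        )

    def test_missing_purity_names_the_sample(self, small_dataset):
        ds = small_dataset
        purity = ds.true_purities.drop(ds.true_purities.index[0])
        with pytest.raises(ValueError, match=ds.true_purities.index[0]):
            run_dectp(ds.expression, ds.groups, purity)

    def test_lambda_one_reduces_to_two_sample_form(self):
        rng = np.random.default_rng(4)
        n0, n1 = 6, 5
        Z = rng.normal(size=(20, n0 + n1))
        cols = [f"n{i}" for i in range(n0)] + [f"t{i}" for i in range(n1)]
        df = pd.DataFrame(Z, index=[f"g{i}" for i in range(20)], columns=cols)
        purity = pd.Series(1.0, index=cols[n0:])
        out = run_dectp(df, self.groups_for(df), purity, shrink_weight=0.0)
        x, y = Z[:, :n0], Z[:, n0:]
        s2n = x.var(axis=1, ddof=1) * (n0 - 1) / (n0 - 2)
        s2t = y.var(axis=1, ddof=1) * (n1 - 1) / (n1 - 2)
        expected = (y.mean(axis=1) - x.mean(axis=1)) / np.sqrt(s2n / n0 + s2t / n1)
        np.testing.assert_allclose(out["wald_t"], expected, atol=1e-10)
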