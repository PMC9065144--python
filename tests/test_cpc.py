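"""CPC discovery statistics: PCA, Wald regressions, combination rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxelgwas import (
    ConfigurationError,
    GenotypeMatrix,
    PCBasis,
    SimConfig,
    backproject,
    combine_global_local,
    combine_sum,
    fit_pca,
    per_pc_wald,
    residualize,
    run_cpc,
    significance_threshold,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_region_atlas,
)
from voxelgwas.cpc import PerPCAssoc


def geno_from_matrix(d):
    d = np.asarray(d, dtype=float)
    m = d.shape[1]
    return GenotypeMatrix(dosages=d, positions=1 + np.arange(m) * 1000,
                          chromosomes=np.full(m, "1", dtype=object),
                          ids=np.array([f"s{j}" for j in range(m)], dtype=object))


class TestFitPca:
    def test_rank_one_data_explains_everything(self, rng):
        u = rng.standard_normal(30)
        v = rng.standard_normal(12)
        X = np.outer(u, v)
        basis = fit_pca(X, K=3)
        assert basis.var_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthonormal_columns(self, rng):
        X = rng.standard_normal((40, 15))
        basis = fit_pca(X, K=10)
        gram = basis.eigenvectors.T @ basis.eigenvectors
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.standard_normal((25, 10))
        basis = fit_pca(X, K=10)
        recon = basis.scores @ basis.eigenvectors.T
        assert np.allclose(recon, X - X.mean(axis=0), atol=1e-8)

    def test_eigenvalues_descending_and_scores_consistent(self, rng):
        X = rng.standard_normal((30, 8))
        basis = fit_pca(X, K=5)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)
        assert np.allclose(basis.scores,
                           (X - X.mean(axis=0)) @ basis.eigenvectors, atol=1e-8)

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ConfigurationError):
            fit_pca(rng.standard_normal((5, 10)), K=5)


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        M = rng.standard_normal((20, 3))
        R = residualize(M, np.ones((20, 1)))
        assert np.allclose(R, M - M.mean(axis=0), atol=1e-12)

    def test_covariate_column_residualizes_to_zero(self, rng):
        z = rng.standard_normal(30)
        Z = np.column_stack([np.ones(30), z])
        R = residualize(z, Z)
        assert np.max(np.abs(R)) < 1e-10

    def test_matches_explicit_ols_residuals(self, rng):
        M = rng.standard_normal((6, 2))
        z = rng.standard_normal(6)
        Z = np.column_stack([np.ones(6), z])
        R = residualize(M, Z)
        expected = np.column_stack([
            M[:, j] - Z @ np.linalg.lstsq(Z, M[:, j], rcond=None)[0]
            for j in range(2)])
        assert np.allclose(R, expected, atol=1e-10)
        # residuals orthogonal to every covariate column
        assert np.max(np.abs(Z.T @ R)) < 1e-8

    def test_rank_deficient_design_names_columns(self, rng):
        z = rng.standard_normal(15)
        Z = np.column_stack([np.ones(15), z, 2 * z])
        with pytest.raises(ConfigurationError, match="collinear"):
            residualize(rng.standard_normal(15), Z)


class TestPerPcWald:
    def test_eight_subject_oracle_matches_full_design_ols(self):
        # Frisch-Waugh: marginal stat after residualization == full-design t
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        n = 8
        g = rng.integers(0, 3, (n, 2)).astype(float)
        Z = np.column_stack([np.ones(n), rng.standard_normal(n),
                             rng.standard_normal(n)])
        scores = rng.standard_normal((n, 2))
        basis = PCBasis(eigenvectors=np.eye(2), eigenvalues=np.ones(2),
                        scores=scores, voxel_mean=np.zeros(2),
                        var_explained=np.full(2, 0.5))
        assoc = per_pc_wald(basis, geno_from_matrix(g), Z)
        for j in range(2):
            for k in range(2):
                X = np.column_stack([g[:, j], Z])
                fit = sm.OLS(scores[:, k], X).fit()
                assert assoc.wald[j, k] == pytest.approx(fit.tvalues[0], abs=1e-8)
                assert assoc.beta[j, k] == pytest.approx(fit.params[0], abs=1e-8)

    def test_null_wald_statistics_standard_normal(self):
        # 200 SNPs x 20 PCs under the global null
        cfg = SimConfig(n_subjects=2000, n_snps=200, within_block_r=0.0,
                        missing_rate=0.0, grid_dims=(6, 6, 2), n_latent=0,
                        covariate_effects=(), seed=77)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(7)
        scores = rng.standard_normal((2000, 20))
        basis = PCBasis(eigenvectors=np.eye(20), eigenvalues=np.ones(20),
                        scores=scores, voxel_mean=np.zeros(20),
                        var_explained=np.full(20, 1 / 20))
        Z = np.column_stack([np.ones(2000), rng.standard_normal((2000, 2))])
        assoc = per_pc_wald(basis, G, Z)
        W = assoc.wald.ravel()
        assert abs(W.mean()) < 3 * np.sqrt(1 / W.size)
        assert abs(W.var() - 1) < 0.1

    def test_constant_dosage_flagged(self, rng):
        g = np.column_stack([np.full(50, 1.0), rng.integers(0, 3, 50)])
        scores = rng.standard_normal((50, 3))
        basis = PCBasis(eigenvectors=np.eye(3), eigenvalues=np.ones(3),
                        scores=scores, voxel_mean=np.zeros(3),
                        var_explained=np.full(3, 1 / 3))
        assoc = per_pc_wald(basis, geno_from_matrix(g), np.ones((50, 1)))
        assert not assoc.tested[0]
        assert np.isnan(assoc.wald[0]).all()
        assert assoc.tested[1]


class TestCombineRules:
    def test_all_zero_walds(self):
        T, p = combine_sum(np.zeros(10))
        assert T == 0 and p == 1.0

    def test_chi2_two_df_closed_form(self):
        T, p = combine_sum(np.array([1.0, 2.0]))
        assert T == pytest.approx(5.0)
        assert p == pytest.approx(np.exp(-2.5), abs=1e-12)

    def test_missing_entries_reduce_df(self):
        w = np.array([1.0, np.nan, 2.0])
        T, p = combine_sum(w)
        assert T == pytest.approx(5.0)
        assert p == pytest.approx(np.exp(-2.5), abs=1e-12)

    def test_empty_row_raises(self):
        with pytest.raises(ConfigurationError):
            combine_sum(np.array([np.nan]))

    def test_null_p_values_uniform(self, rng):
        W = rng.standard_normal((400, 20))
        ps = [combine_sum(W[i])[1] for i in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_fisher_all_null_heads(self):
        X, p = combine_global_local(np.zeros(10), C=4)
        assert X == 0.0 and p == 1.0

    def test_fisher_median_heads_closed_form(self):
        # construct W so both head and tail chi2 p-values are exactly 0.5
        w1 = np.sqrt(stats.chi2.isf(0.5, 1))
        w = np.array([w1, w1])
        X, p = combine_global_local(w, C=1)
        assert X == pytest.approx(2.77259, abs=1e-4)
        assert p == pytest.approx((1 + X / 2) * np.exp(-X / 2), abs=1e-10)

    def test_fisher_null_uniform_with_independent_blocks(self, rng):
        W = rng.standard_normal((400, 20))
        ps = [combine_global_local(W[i], C=5)[1] for i in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cut_at_or_beyond_k_falls_back(self):
        w = np.array([1.0, 2.0])
        with pytest.warns(UserWarning, match="falling back"):
            X, p = combine_global_local(w, C=2)
        assert X == pytest.approx(5.0)


class TestRunCpc:
    def make_assoc(self, W):
        m, K = W.shape
        return PerPCAssoc(beta=W.copy(), se=np.ones_like(W), wald=W,
                          snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
                          df_resid=100, tested=np.ones(m, dtype=bool))

    def test_paper_default_threshold(self):
        assert significance_threshold(4, 3) == pytest.approx(5e-8 / 12, rel=1e-12)

    def test_strong_snp_significant_at_corrected_alpha(self, rng):
        W = rng.standard_normal((20, 12)) * 0.5
        W[3] = 8.0  # enormous signal on every PC
        res = run_cpc(self.make_assoc(W), cut_points=(3, 6), alpha=4.2e-9)
        assert res.table.loc[3, "significant"]
        assert res.table.loc[3, "best_p"] < 1e-10

    def test_null_walds_not_significant(self, rng):
        W = rng.standard_normal((50, 12))
        res = run_cpc(self.make_assoc(W), cut_points=(3, 6), alpha="auto",
                      n_features=3)
        assert res.n_significant == 0
        assert res.alpha == pytest.approx(5e-8 / 6)

    def test_rotation_invariance_of_full_sum(self, rng):
        # orthogonal rotation of unit-variance components leaves the omnibus
        # statistic invariant (asymptotically; W^2 = df r^2/(1-r^2))
        n, K = 3000, 10
        raw = rng.standard_normal((n, K))
        raw -= raw.mean(axis=0)
        scores, _ = np.linalg.qr(raw)      # exactly orthogonal, like PC scores
        scores *= np.sqrt(n)
        q, _ = np.linalg.qr(rng.standard_normal((K, K)))
        g = rng.integers(0, 3, (n, 5)).astype(float)
        Z = np.ones((n, 1))
        stat = {}
        for name, S in (("base", scores), ("rot", scores @ q)):
            basis = PCBasis(eigenvectors=np.eye(K), eigenvalues=np.ones(K),
                            scores=S, voxel_mean=np.zeros(K),
                            var_explained=np.full(K, 1 / K))
            assoc = per_pc_wald(basis, geno_from_matrix(g), Z)
            stat[name] = np.array([combine_sum(assoc.wald[j])[0] for j in range(5)])
        assert np.allclose(stat["base"], stat["rot"], rtol=5e-3)

    def test_power_monotone_in_effect_size(self):
        # mean omnibus statistic grows with the causal effect (50 replicates)
        atlas = simulate_region_atlas((6, 6, 2), 4, smoothness=0, seed=1)
        means = {}
        for beta in (0.15, 0.5):
            stats_ = []
            for rep in range(50):
                cfg = SimConfig(n_subjects=300, n_snps=5, grid_dims=(6, 6, 2),
                                n_latent=1, covariate_effects=(),
                                within_block_r=0.0, missing_rate=0.0,
                                causal_spec=(
                                    __import__("voxelgwas").CausalEffect(2, "region_001", beta),),
                                seed=500 + rep)
                G = simulate_genotypes(cfg)
                Y, Zt, _ = simulate_phenotypes(G, atlas, cfg)
                basis = fit_pca(Y, K=8)
                assoc = per_pc_wald(basis, G, np.ones((300, 1)))
                stats_.append(combine_sum(assoc.wald[2])[0])
            means[beta] = np.mean(stats_)
        assert means[0.5] > means[0.15]


class TestBackproject:
    def make_basis(self, rng, v=6, K=4):
        V, _ = np.linalg.qr(rng.standard_normal((v, K)))
        return PCBasis(eigenvectors=V, eigenvalues=np.ones(K),
                       scores=np.zeros((1, K)), voxel_mean=np.zeros(v),
                       var_explained=np.full(K, 1 / K))

    def test_unit_vector_recovers_eigenvector(self, rng):
        basis = self.make_basis(rng)
        beta = np.array([1.0, 0, 0, 0])
        assert np.allclose(backproject(basis, beta), basis.eigenvectors[:, 0])

    def test_linearity(self, rng):
        basis = self.make_basis(rng)
        b1, b2 = rng.standard_normal(4), rng.standard_normal(4)
        assert np.allclose(backproject(basis, b1 + b2),
                           backproject(basis, b1) + backproject(basis, b2))

    def test_full_rank_equals_voxelwise_regression(self, rng):
        # change of basis: with K = rank and no covariates the back-projected
        # per-PC coefficients equal direct voxelwise simple-regression slopes
        n, v = 12, 5
        Y = rng.standard_normal((n, v))
        g = rng.integers(0, 3, (n, 1)).astype(float)
        basis = fit_pca(Y, K=5)
        assoc = per_pc_wald(basis, geno_from_matrix(g), np.ones((n, 1)))
        bp = backproject(basis, assoc.beta[0])
        gc = g[:, 0] - g[:, 0].mean()
        direct = (gc @ (Y - Y.mean(axis=0))) / (gc @ gc)
        assert np.allclose(bp, direct, atol=1e-8)
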