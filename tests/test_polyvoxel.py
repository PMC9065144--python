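"""Polyvoxel scoring and confirmatory validation in independent samples."""

import numpy as np
import pandas as pd
import pytest

from voxelgwas import (
    CausalEffect,
    PCBasis,
    SimConfig,
    confirmatory_test,
    fit_pca,
    per_pc_wald,
    polyvoxel_score,
    simulate_region_atlas,
    simulate_study,
    validate_loci,
)
from voxelgwas.cpc import run_cpc, summary_stats
from voxelgwas.datatypes import ConfigurationError
from voxelgwas.qc import clump_loci


def identity_basis(v, mean=None):
    return PCBasis(eigenvectors=np.eye(v), eigenvalues=np.ones(v),
                   scores=np.zeros((1, v)), voxel_mean=mean or np.zeros(v),
                   var_explained=np.full(v, 1 / v))


class TestPolyvoxelScore:
    def test_hand_arithmetic(self):
        # v1=(1,0), v2=(0,1), centered x=(3,4), beta=(1,-1) -> 3 - 4 = -1
        basis = identity_basis(2)
        x = np.array([[3.0, 4.0]])
        assert polyvoxel_score(x, basis, np.array([1.0, -1.0]))[0] == pytest.approx(-1.0)

    def test_zero_weights_give_zero_scores(self, rng):
        basis = identity_basis(4)
        X = rng.standard_normal((10, 4))
        assert np.allclose(polyvoxel_score(X, basis, np.zeros(4)), 0.0)

    def test_linearity_in_weights(self, rng):
        basis = identity_basis(4)
        X = rng.standard_normal((10, 4))
        b = rng.standard_normal(4)
        assert np.allclose(polyvoxel_score(X, basis, 2 * b),
                           2 * polyvoxel_score(X, basis, b))

    def test_discovery_means_used_for_centering(self, rng):
        v = 3
        mean = np.array([10.0, -5.0, 2.0])
        basis = PCBasis(eigenvectors=np.eye(v), eigenvalues=np.ones(v),
                        scores=np.zeros((1, v)), voxel_mean=mean,
                        var_explained=np.full(v, 1 / 3))
        X = np.tile(mean, (5, 1))
        assert np.allclose(polyvoxel_score(X, basis, np.ones(v)), 0.0)

    def test_grid_mismatch_raises(self, rng):
        from voxelgwas import PhenotypeVolumeSet
        basis = identity_basis(8)
        basis.grid_dims = (2, 2, 2)
        Y = PhenotypeVolumeSet(values=rng.standard_normal((4, 8)), grid_dims=(4, 2, 1))
        with pytest.raises(ConfigurationError):
            polyvoxel_score(Y, basis, np.ones(8))


class TestConfirmatoryTest:
    def test_in_sample_covariance_identity(self):
        # covariate-free discovery: cov(g, score) = var(g) * sum beta_k^2
        cfg = SimConfig(n_subjects=400, n_snps=20, missing_rate=0.0,
                        grid_dims=(5, 4, 2), n_latent=2, covariate_effects=(),
                        seed=55)
        from voxelgwas import simulate_genotypes, simulate_phenotypes
        G = simulate_genotypes(cfg)
        atlas = simulate_region_atlas(cfg.grid_dims, 3, seed=1)
        Y, _, _ = simulate_phenotypes(G, atlas, cfg)
        basis = fit_pca(Y, K=10)
        Z = np.ones((400, 1))
        assoc = per_pc_wald(basis, G, Z)
        for j in range(G.n_snps):
            score = polyvoxel_score(Y, basis, assoc.beta[j])
            g = G.dosages[:, j]
            n = len(g)
            cov_gs = np.sum((g - g.mean()) * (score - score.mean())) / n
            var_g = np.sum((g - g.mean()) ** 2) / n
            assert cov_gs == pytest.approx(var_g * np.sum(assoc.beta[j] ** 2),
                                           abs=1e-10 * max(1, abs(cov_gs)))

    def test_permutation_null_controls_t(self, rng):
        n = 1000
        g = rng.integers(0, 3, n).astype(float)
        score = g * 0.5 + rng.standard_normal(n)
        Z = np.ones((n, 1))
        big = 0
        for _ in range(100):
            perm = rng.permutation(score)
            t, p, ok = confirmatory_test(g, perm, Z)
            big += abs(t) >= 3
        assert big <= 1  # |t| < 3 in >= 99% of permutations

    def test_direction_invariance(self, rng):
        n = 200
        g = rng.integers(0, 3, n).astype(float)
        s = 0.3 * g + rng.standard_normal(n)
        Z = np.column_stack([np.ones(n), rng.standard_normal(n)])
        t1, p1, _ = confirmatory_test(g, s, Z)
        t2, p2, _ = confirmatory_test(s, g, Z)
        assert abs(t1) == pytest.approx(abs(t2), abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_dosage_not_testable(self, rng):
        res = confirmatory_test(np.ones(50), rng.standard_normal(50), np.ones((50, 1)))
        assert not res.testable


def run_discovery_in_memory(study, K=10, alpha=4.2e-9):
    G, Y, Z = study.discovery
    basis = fit_pca(Y, K=K)
    assoc = per_pc_wald(basis, G, Z)
    cpc = run_cpc(assoc, cut_points=(3, 5), alpha=alpha)
    ss = summary_stats(cpc, G)
    loci = clump_loci(ss, G, p_thresh=alpha)
    return basis, assoc, loci


class TestValidateLoci:
    def test_bonferroni_arithmetic(self, rng):
        # 10 loci -> per-locus alpha 0.005
        cfg = SimConfig(n_subjects=100, n_snps=12, missing_rate=0.0,
                        grid_dims=(4, 4, 2), seed=3)
        study = simulate_study(cfg, n_validation=100)
        basis = fit_pca(study.validation.phenotypes, K=5)
        assoc = per_pc_wald(basis, study.validation.genotypes,
                            study.validation.covariates)
        loci = pd.DataFrame([{"chr": "1", "start": j, "end": j,
                              "lead_snp": f"snp{j:05d}", "lead_pos": j,
                              "min_p": 1e-10} for j in range(10)])
        report = validate_loci(loci, study.validation.phenotypes,
                               study.validation.genotypes,
                               study.validation.covariates, basis, assoc)
        assert np.allclose(report["alpha"], 0.005)

    def test_causal_locus_validates_with_high_power(self):
        # locus led by the causal SNP, scored with discovery-sample weights,
        # replicates in an independent n=2000 sample in >= 95% of 50 runs
        validated = 0
        atlas = simulate_region_atlas((5, 4, 2), 3, smoothness=1.0, seed=2)
        for rep in range(50):
            cfg = SimConfig(n_subjects=1000, n_snps=30, grid_dims=(5, 4, 2),
                            n_latent=2, within_block_r=0.3, missing_rate=0.0,
                            maf_range=(0.2, 0.5),
                            causal_spec=(CausalEffect(7, "region_001", 0.8),),
                            seed=7000 + rep)
            study = simulate_study(cfg, atlas=atlas, n_validation=2000)
            basis = fit_pca(study.discovery.phenotypes, K=20)
            assoc = per_pc_wald(basis, study.discovery.genotypes,
                                study.discovery.covariates)
            loci = pd.DataFrame([{"chr": "1", "start": 70_001, "end": 70_001,
                                  "lead_snp": "snp00007", "lead_pos": 70_001,
                                  "min_p": 1e-10}])
            report = validate_loci(loci, study.validation.phenotypes,
                                   study.validation.genotypes,
                                   study.validation.covariates, basis, assoc)
            validated += int(report.iloc[0]["validated"])
        assert validated >= 48  # >= 95% of 50 replicates

    def test_null_locus_validates_at_alpha_rate(self, rng):
        # a locus "discovered" by construction on a null SNP replicates at
        # roughly the per-locus alpha
        atlas = simulate_region_atlas((4, 4, 2), 3, seed=1)
        hits = 0
        reps = 60
        for rep in range(reps):
            cfg = SimConfig(n_subjects=400, n_snps=10, grid_dims=(4, 4, 2),
                            n_latent=2, missing_rate=0.0, seed=9000 + rep)
            study = simulate_study(cfg, atlas=atlas, n_validation=400)
            basis = fit_pca(study.discovery.phenotypes, K=6)
            assoc = per_pc_wald(basis, study.discovery.genotypes,
                                study.discovery.covariates)
            loci = pd.DataFrame([{"chr": "1", "start": 1, "end": 1,
                                  "lead_snp": "snp00003", "lead_pos": 1,
                                  "min_p": 1e-10}])
            report = validate_loci(loci, study.validation.phenotypes,
                                   study.validation.genotypes,
                                   study.validation.covariates, basis, assoc)
            hits += int(report.iloc[0]["validated"])
        # alpha = 0.05; 3-sigma binomial envelope around the expected rate
        assert hits / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_missing_lead_reported_untestable(self, rng):
        cfg = SimConfig(n_subjects=100, n_snps=8, missing_rate=0.0,
                        grid_dims=(4, 4, 2), seed=5)
        study = simulate_study(cfg)
        basis = fit_pca(study.validation.phenotypes, K=4)
        assoc = per_pc_wald(basis, study.validation.genotypes,
                            study.validation.covariates)
        loci = pd.DataFrame([{"chr": "1", "start": 1, "end": 1,
                              "lead_snp": "absent_snp", "lead_pos": 1,
                              "min_p": 1e-10}])
        report = validate_loci(loci, study.validation.phenotypes,
                               study.validation.genotypes,
                               study.validation.covariates, basis, assoc)
        assert not report.iloc[0]["testable"]
        assert not report.iloc[0]["validated"]
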