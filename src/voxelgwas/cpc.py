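"""Combined principal component (CPC) multivariate GWAS.

The discovery-stage statistic: voxelwise phenotypes are reduced to K
principal components; each SNP is tested against each PC score with
covariate adjustment, giving a Wald statistic W_k per PC.  Because PC
scores are mutually orthogonal, the sum of squared Wald statistics over K
PCs follows a chi-square distribution with K degrees of freedom under the
null, giving a closed-form omnibus p-value without permutations.

A "global-local" family of combination rules splits the PCs at a cut
point C: the head (first C PCs, the high-variance global modes) and the
tail (remaining K - C) each yield a chi-square p-value, and the two are
combined by Fisher's method (chi-square with 4 df).  Scanning several cut
points trades sensitivity between concentrated and diffuse signals; the
significance threshold is Bonferroni-adjusted for the number of rules
scanned times the number of tissue features analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigurationError,
    CovariateTable,
    GenotypeMatrix,
    PhenotypeVolumeSet,
)

GENOME_WIDE_ALPHA = 5e-8


def significance_threshold(n_rules: int, n_features: int,
                           base: float = GENOME_WIDE_ALPHA) -> float:
    """Genome-wide alpha Bonferroni-adjusted for rule scanning and features."""
    if n_rules < 1 or n_features < 1:
        raise ConfigurationError("n_rules and n_features must be >= 1")
    return base / (n_rules * n_features)


@dataclass
class PCBasis:
    """Voxel-space PCA basis: eigenvectors, eigenvalues, subject scores."""

    eigenvectors: np.ndarray       # (n_voxels, K), orthonormal columns
    eigenvalues: np.ndarray        # (K,), descending
    scores: np.ndarray             # (n_subjects, K)
    voxel_mean: np.ndarray         # (n_voxels,)
    var_explained: np.ndarray      # (K,) fraction of total variance
    grid_dims: tuple[int, int, int] | None = None

    @property
    def K(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.eigenvectors.shape[0]

    def cumulative_var_explained(self) -> np.ndarray:
        return np.cumsum(self.var_explained)


def fit_pca(Y: PhenotypeVolumeSet | np.ndarray, K: int) -> PCBasis:
    """Top-K PCA of the subject x voxel matrix via thin SVD.

    Column signs are fixed so the largest-magnitude loading of each
    eigenvector is positive, making the decomposition deterministic.
    Eigenvalues are sample variances of the scores (divisor n - 1).
    """
    if isinstance(Y, PhenotypeVolumeSet):
        X = Y.values
        grid = Y.grid_dims
    else:
        X = np.asarray(Y, dtype=float)
        grid = None
    n, v = X.shape
    if K > min(n - 1, v):
        raise ConfigurationError(f"K={K} exceeds min(n-1, voxels)={min(n - 1, v)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s ** 2) / (n - 1))
    V = Vt[:K].T
    s = s[:K]
    # sign convention: largest-|loading| entry positive
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = U[:, :K] * s * flip
    eigenvalues = s ** 2 / (n - 1)
    return PCBasis(eigenvectors=V, eigenvalues=eigenvalues, scores=scores,
                   voxel_mean=mean,
                   var_explained=eigenvalues / total_var if total_var > 0 else eigenvalues,
                   grid_dims=grid)


def _design(Z: CovariateTable | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(Z, CovariateTable):
        return Z.design_matrix()
    Z = np.asarray(Z, dtype=float)
    return Z, [f"z{j}" for j in range(Z.shape[1])]


def residualize(M: np.ndarray, Z: CovariateTable | np.ndarray) -> np.ndarray:
    """Project out covariate columns: M - Z (Z'Z)^-1 Z' M.

    Raises if the design (including intercept) is rank deficient, naming
    the collinear columns.
    """
    D, names = _design(Z)
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    q, r, piv = _qr_rank(D)
    rank = q.shape[1]
    if rank < D.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ConfigurationError(f"collinear covariate columns: {bad}")
    return M - q @ (q.T @ M)


def _qr_rank(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-revealing QR; returns (Q restricted to rank, R, pivot)."""
    from scipy.linalg import qr

    q, r, piv = qr(D, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(D.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return q[:, :rank], r, piv


@dataclass
class PerPCAssoc:
    """SNP x PC regression summaries (coefficients of score on dosage)."""

    beta: np.ndarray               # (n_snps, K)
    se: np.ndarray                 # (n_snps, K)
    wald: np.ndarray               # (n_snps, K)
    snp_ids: np.ndarray
    df_resid: int
    tested: np.ndarray             # (n_snps,) False where residual dosage variance was 0

    @property
    def n_snps(self) -> int:
        return self.beta.shape[0]

    @property
    def K(self) -> int:
        return self.beta.shape[1]

    def snp_row(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in association results")
        return int(hits[0])


def per_pc_wald(basis: PCBasis, G: GenotypeMatrix,
                Z: CovariateTable | np.ndarray) -> PerPCAssoc:
    """Covariate-adjusted marginal association of every SNP with every PC score.

    Missing dosages are mean-imputed per SNP; dosages and PC scores are both
    residualized on the covariate design (Frisch-Waugh), after which the
    simple-regression slope of score on dosage, its standard error, and the
    Wald statistic W = beta / se equal the full-design multiple-regression
    quantities.  SNPs with zero residual dosage variance are flagged
    untested with NaN statistics.
    """
    D, _ = _design(Z)
    n = G.n_subjects
    if basis.scores.shape[0] != n or D.shape[0] != n:
        raise ConfigurationError("subject counts differ across inputs")
    S_r = residualize(basis.scores, Z)
    G_r = residualize(G.imputed_dosages(), Z)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    ss = np.einsum("ik,ik->k", S_r, S_r)
    cross = G_r.T @ S_r                               # (m, K)
    df = n - D.shape[1] - 1
    if df <= 0:
        raise ConfigurationError("not enough subjects for the covariate design")

    tested = gg > n * 1e-12
    safe_gg = np.where(tested, gg, np.nan)
    beta = cross / safe_gg[:, None]
    rss = np.clip(ss[None, :] - beta ** 2 * safe_gg[:, None], 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / df / safe_gg[:, None])
        wald = np.where(se > 0, beta / se, np.nan)
    return PerPCAssoc(beta=beta, se=se, wald=wald, snp_ids=G.ids,
                      df_resid=df, tested=tested)


def combine_sum(w_row: np.ndarray) -> tuple[float, float]:
    """Full-sum omnibus: T = sum W_k^2 ~ chi-square with K df under the null.

    Missing (NaN) entries are dropped and the degrees of freedom reduced
    accordingly; an all-missing row is an error.
    """
    w = np.asarray(w_row, dtype=float)
    w = w[np.isfinite(w)]
    if w.size == 0:
        raise ConfigurationError("no finite Wald statistics to combine")
    T = float(np.sum(w ** 2))
    return T, float(stats.chi2.sf(T, df=w.size))


def combine_global_local(w_row: np.ndarray, C: int) -> tuple[float, float]:
    """Head/tail Fisher combination at cut point C.

    The first C PCs and the remaining K - C PCs each give a chi-square
    upper-tail p; X = -2 (ln p_head + ln p_tail) ~ chi-square with 4 df.
    ``C >= K`` falls back to the full sum with a warning.
    """
    w = np.asarray(w_row, dtype=float)
    K = w.size
    if C < 1:
        raise ConfigurationError("cut point must be >= 1")
    if C >= K:
        warnings.warn(f"cut point {C} >= K={K}; falling back to full-sum rule",
                      stacklevel=2)
        return combine_sum(w)
    _, p_head = combine_sum(w[:C])
    _, p_tail = combine_sum(w[C:])
    # clip to avoid log(0) from underflowed tails
    tiny = np.finfo(float).tiny
    X = -2.0 * (np.log(max(p_head, tiny)) + np.log(max(p_tail, tiny)))
    return float(X), float(stats.chi2.sf(X, df=4))


@dataclass
class CPCResult:
    """Per-SNP combined statistics for every rule plus the best-rule call."""

    table: pd.DataFrame
    alpha: float
    cut_points: tuple[int, ...]
    K: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def run_cpc(assoc: PerPCAssoc, cut_points: tuple[int, ...] = (5, 10),
            alpha: float | str = "auto", n_features: int = 1) -> CPCResult:
    """Apply the full-sum and global-local rules to every SNP.

    The candidate rules for significance calling are the global-local cut
    points when any are given (the full sum is still reported); with
    ``alpha="auto"`` the threshold is 5e-8 / (n_rules * n_features), the
    Bonferroni adjustment for rule scanning across features.
    """
    cut_points = tuple(int(c) for c in cut_points)
    for c in cut_points:
        if not 1 <= c < assoc.K:
            raise ConfigurationError(f"cut point {c} must satisfy 1 <= C < K={assoc.K}")
    n_rules = len(cut_points) if cut_points else 1
    if alpha == "auto":
        alpha_val = significance_threshold(n_rules, n_features)
    else:
        alpha_val = float(alpha)

    rows = []
    for i in range(assoc.n_snps):
        rec: dict = {"snp": assoc.snp_ids[i]}
        if not assoc.tested[i]:
            rec.update(stat_sum=np.nan, p_sum=np.nan, best_rule=None,
                       best_p=np.nan, significant=False)
            for c in cut_points:
                rec[f"stat_c{c}"] = np.nan
                rec[f"p_c{c}"] = np.nan
            rows.append(rec)
            continue
        T, p = combine_sum(assoc.wald[i])
        rec["stat_sum"], rec["p_sum"] = T, p
        candidates: list[tuple[float, str, float]] = []
        if not cut_points:
            candidates.append((p, "sum", T))
        for c in cut_points:
            X, pc = combine_global_local(assoc.wald[i], c)
            rec[f"stat_c{c}"], rec[f"p_c{c}"] = X, pc
            candidates.append((pc, f"fisher_c{c}", X))
        best_p, best_rule, best_stat = min(candidates, key=lambda t: t[0])
        rec["best_rule"] = best_rule
        rec["best_p"] = best_p
        rec["best_stat"] = best_stat
        rec["significant"] = bool(best_p < alpha_val)
        rows.append(rec)
    return CPCResult(table=pd.DataFrame(rows), alpha=alpha_val,
                     cut_points=cut_points, K=assoc.K)


def summary_stats(result: CPCResult, G: GenotypeMatrix,
                  feature: str = "pheno") -> pd.DataFrame:
    """Flatten a CPCResult into a summary-statistics table (one row per SNP)."""
    t = result.table
    order = [G.snp_index(s) for s in t["snp"]]
    return pd.DataFrame({
        "snp": t["snp"].to_numpy(),
        "chr": G.chromosomes[order],
        "pos": G.positions[order],
        "a1": G.ref[order],
        "a2": G.alt[order],
        "stat": t.get("best_stat", t["stat_sum"]).to_numpy(),
        "p": t["best_p"].to_numpy(),
        "feature": feature,
        "rule": t["best_rule"].to_numpy(),
    })


def backproject(basis: PCBasis, beta_row: np.ndarray,
                K_use: int | None = None) -> np.ndarray:
    """Back-project per-PC coefficients into voxel space: beta_i = sum_k beta_k v_ki."""
    beta_row = np.asarray(beta_row, dtype=float)
    K_use = basis.K if K_use is None else int(K_use)
    if K_use > basis.K:
        raise ConfigurationError(f"K_use={K_use} exceeds basis K={basis.K}")
    return basis.eigenvectors[:, :K_use] @ beta_row[:K_use]
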