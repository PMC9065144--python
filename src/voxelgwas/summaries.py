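"""Genome-wide summary analytics on multivariate GWAS output.

* LD scores (sum of r^2 with windowed neighbors, self included) and a
  simple LD-score regression: E[chi2_j] = 1 + n h2 l_j / M fitted by
  ordinary least squares with a free intercept, slope converted to h2 by
  M / n, standard error by delete-one-block jackknife.
* Eigenvalue-weighted average heritability across PCs -- the natural
  summary of the genetic architecture of a high-dimensional phenotype.
* Rescaling of the K-df multivariate chi-square to unit null mean (T / K)
  so it can enter stratified LDSC-style regressions.
* Unsigned genome-wide signal overlap between two traits: the Spearman
  correlation of per-LD-block mean -log10 p profiles.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, GenotypeMatrix

NEGLOG10_CAP = 320.0


def compute_ld_scores(G: GenotypeMatrix, window_bp: int = 1_000_000,
                      blocks: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP LD scores: l_j = sum of r^2 with SNPs within the window.

    The self term (r^2 = 1) is always included, so l_j >= 1; a window of 0
    gives l_j = 1 for every SNP.  r^2 uses mean-imputed dosages.  ``blocks``
    defaults to the generative block ids carried by the genotype matrix.
    """
    d = G.imputed_dosages()
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    nz = sd > 0
    ell = np.ones(G.n_snps)
    for chrom in pd.unique(G.chromosomes):
        idx = np.flatnonzero((G.chromosomes == chrom) & nz)
        if idx.size < 2:
            continue
        X = d[:, idx] / sd[idx]
        r2 = (X.T @ X / X.shape[0]) ** 2
        pos = G.positions[idx]
        within = np.abs(np.subtract.outer(pos, pos)) <= window_bp
        np.fill_diagonal(within, False)
        ell[idx] = 1.0 + (r2 * within).sum(axis=1)
    if blocks is None:
        blocks = G.block_ids if G.block_ids is not None else np.zeros(G.n_snps, dtype=int)
    return pd.DataFrame({"snp": G.ids, "chr": G.chromosomes, "pos": G.positions,
                         "block": np.asarray(blocks), "ell": ell})


class H2Estimate(NamedTuple):
    h2: float
    se: float
    intercept: float
    n_blocks: int


def ldsc_h2(chi2: np.ndarray, ld: pd.DataFrame, n: int, M: int) -> H2Estimate:
    """LD-score regression heritability with block-jackknife standard error.

    Fits chi2_j = a + b l_j by unweighted least squares; h2 = b M / n.
    The SE comes from delete-one-block jackknife over the ``block`` column
    of ``ld``.  Raises if the LD scores have no variation (slope
    unidentifiable) or fewer than two blocks exist.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = ld["ell"].to_numpy(dtype=float)
    if chi2.shape[0] != ell.shape[0]:
        raise ConfigurationError("chi2 and LD-score table lengths differ")
    if np.var(ell) == 0:
        raise ConfigurationError("LD scores have no variation; slope unidentifiable")
    blocks = ld["block"].to_numpy()
    uniq = pd.unique(blocks)
    if uniq.size < 2:
        raise ConfigurationError("need >= 2 LD blocks for the jackknife")

    def slope(mask: np.ndarray) -> float:
        x, y = ell[mask], chi2[mask]
        xm = x - x.mean()
        return float((xm @ y) / (xm @ xm))

    all_mask = np.ones_like(ell, dtype=bool)
    b_full = slope(all_mask)
    intercept = float(chi2.mean() - b_full * ell.mean())
    h2 = b_full * M / n

    jk = []
    for u in uniq:
        mask = blocks != u
        if np.var(ell[mask]) == 0:
            continue
        jk.append(slope(mask) * M / n)
    jk = np.asarray(jk)
    B = jk.size
    if B < 2:
        raise ConfigurationError("too few informative blocks for the jackknife")
    se = float(np.sqrt((B - 1) / B * np.sum((jk - jk.mean()) ** 2)))
    return H2Estimate(h2=float(h2), se=se, intercept=intercept, n_blocks=int(B))


def average_h2(h2_per_pc: np.ndarray, eigenvalues: np.ndarray) -> float:
    """Eigenvalue-weighted average heritability: sum(l_k h2_k) / sum(l_k)."""
    h2 = np.asarray(h2_per_pc, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if h2.shape != lam.shape:
        raise ConfigurationError("h2 and eigenvalue lengths differ")
    if np.any(lam < 0):
        raise ConfigurationError("eigenvalues must be non-negative")
    total = lam.sum()
    if total <= 0:
        raise ConfigurationError("eigenvalues sum to zero")
    return float((lam * h2).sum() / total)


def scaled_chi2(T: np.ndarray | float, K: int) -> np.ndarray | float:
    """Rescale the K-df multivariate chi-square to unit null mean (T / K)."""
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    return np.asarray(T, dtype=float) / K if np.ndim(T) else float(T) / K


def block_profile(ss: pd.DataFrame, blocks: np.ndarray | None = None) -> pd.Series:
    """Per-LD-block mean of -log10 p across member SNPs.

    ``ss`` needs columns ``p`` and (unless ``blocks`` is given) ``block``.
    -log10 p is capped at 320 to absorb underflowed p-values; empty blocks
    simply do not appear.
    """
    p = ss["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        p = np.clip(p, 10.0 ** (-NEGLOG10_CAP), 1.0)
    neglog = np.minimum(-np.log10(p), NEGLOG10_CAP)
    b = np.asarray(blocks) if blocks is not None else ss["block"].to_numpy()
    return pd.Series(neglog).groupby(pd.Series(b)).mean().rename("mean_neglog10p")


class OverlapResult(NamedTuple):
    rho: float
    p: float
    n_blocks: int


def overlap_rho(a: pd.Series, b: pd.Series) -> OverlapResult:
    """Spearman correlation of two block signal profiles (shared blocks only)."""
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ConfigurationError("need >= 3 shared blocks for Spearman correlation")
    rho, p = stats.spearmanr(joined["a"], joined["b"])
    return OverlapResult(rho=float(rho), p=float(p), n_blocks=len(joined))
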