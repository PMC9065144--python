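"""Regional enrichment of a SNP's voxelwise association pattern.

The enrichment score of a back-projected coefficient map beta_i for a
region with voxel probability map P_i is the probability-weighted mean

    score = sum_i P_i beta_i / sum_i P_i .

Its null distribution is estimated empirically by bootstrapping whole
association maps from SNPs that did not reach significance: each bootstrap
draw picks one non-significant SNP map (with replacement) and scores it,
so the null mean and SD describe the score of a typical null SNP while
preserving the spatial correlation of association patterns.  The z-score
(score - mu0) / sigma0 and a two-sided normal p-value localize where a
discovered SNP's multivariate signal concentrates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, RegionAtlas

MIN_NULL_MAPS = 50


def enrichment_score(beta_map: np.ndarray, prob_map: np.ndarray) -> float:
    """Probability-weighted mean of the coefficient map over one region."""
    P = np.asarray(prob_map, dtype=float)
    b = np.asarray(beta_map, dtype=float)
    total = P.sum()
    if total <= 0:
        raise ConfigurationError("probability map sums to zero")
    return float((P * b).sum() / total)


def _apply_weighting(maps: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "signed":
        return maps
    if weighting == "abs":
        return np.abs(maps)
    if weighting == "squared":
        return maps ** 2
    raise ConfigurationError(f"unknown weighting {weighting!r}")


def bootstrap_null(nonsig_maps: np.ndarray, prob_map: np.ndarray,
                   B: int = 1000, seed: int = 0,
                   min_maps: int = MIN_NULL_MAPS) -> tuple[float, float]:
    """Bootstrap null mean and SD of the enrichment score.

    ``nonsig_maps`` is (n_maps, n_voxels): whole association maps of SNPs
    below the significance threshold.  Each of the B draws resamples one
    map with replacement and computes its enrichment score.
    """
    maps = np.atleast_2d(np.asarray(nonsig_maps, dtype=float))
    if maps.shape[0] < min_maps:
        raise ConfigurationError(
            f"need >= {min_maps} non-significant maps, got {maps.shape[0]}")
    if B < 100:
        raise ConfigurationError("B must be >= 100")
    P = np.asarray(prob_map, dtype=float)
    total = P.sum()
    if total <= 0:
        raise ConfigurationError("probability map sums to zero")
    scores = maps @ P / total
    rng = np.random.default_rng(seed)
    draws = scores[rng.integers(0, maps.shape[0], size=B)]
    mu0 = float(draws.mean())
    sd0 = float(draws.std(ddof=1))
    if sd0 == 0:
        warnings.warn("degenerate bootstrap null: zero variance across maps",
                      stacklevel=2)
    return mu0, sd0


def enrichment_profile(snp_map: np.ndarray, nonsig_maps: np.ndarray,
                       atlas: RegionAtlas, B: int = 1000, seed: int = 0,
                       weighting: str = "signed",
                       min_maps: int = MIN_NULL_MAPS) -> pd.DataFrame:
    """Per-region enrichment z-scores and p-values for one SNP map.

    Regions are ranked by |z| descending (rank 1 = most enriched).
    ``weighting`` selects how coefficient magnitudes enter the score:
    ``signed`` (as-is), ``abs``, or ``squared``.
    """
    if atlas.n_regions == 0:
        raise ConfigurationError("empty atlas")
    snp_w = _apply_weighting(np.asarray(snp_map, dtype=float), weighting)
    null_w = _apply_weighting(np.atleast_2d(np.asarray(nonsig_maps, dtype=float)),
                              weighting)
    rows = []
    for k in range(atlas.n_regions):
        P = atlas.probs[k]
        score = enrichment_score(snp_w, P)
        # one shared seed: identical probability maps then tie exactly
        mu0, sd0 = bootstrap_null(null_w, P, B=B, seed=seed, min_maps=min_maps)
        z = (score - mu0) / sd0 if sd0 > 0 else float("inf") if score != mu0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        rows.append({"region": atlas.names[k], "score": score,
                     "mu0": mu0, "sd0": sd0, "z": z, "p": p})
    out = pd.DataFrame(rows)
    order = np.argsort(-np.abs(out["z"].to_numpy()), kind="stable")
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out


def top_regions(profile: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k most-enriched regions by |z| (the profile's rank order)."""
    return profile.sort_values("rank", kind="mergesort").head(k).reset_index(drop=True)
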