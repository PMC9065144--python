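"""Confirmatory polyvoxel-score validation of discovered loci.

For a discovered SNP, the discovery-sample eigenvectors v_k and per-PC
regression coefficients beta_k define a per-subject scalar score

    score = sum_k beta_k v_k' x

where x is the raw voxel data of a validation subject, centered by the
DISCOVERY voxel means.  Regressing the validation-sample dosage of the
same SNP on this score (with covariates) is a one-degree-of-freedom test
of whether the multivariate effect pattern replicates; validation uses a
Bonferroni threshold of 0.05 over the number of loci discovered for the
feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cpc import PCBasis, PerPCAssoc, residualize, _design
from .datatypes import ConfigurationError, CovariateTable, GenotypeMatrix, PhenotypeVolumeSet


def polyvoxel_score(X_raw: PhenotypeVolumeSet | np.ndarray, basis: PCBasis,
                    beta_row: np.ndarray, K_use: int | None = None) -> np.ndarray:
    """Per-subject polyvoxel score from discovery eigenvectors and coefficients.

    ``X_raw`` is raw (uncentered) voxel data; centering uses the discovery
    voxel means stored in ``basis`` so the score is portable to a new
    sample on the same voxel grid.
    """
    if isinstance(X_raw, PhenotypeVolumeSet):
        if basis.grid_dims is not None and tuple(X_raw.grid_dims) != tuple(basis.grid_dims):
            raise ConfigurationError(
                f"voxel grid {X_raw.grid_dims} does not match discovery grid {basis.grid_dims}")
        X = X_raw.values
    else:
        X = np.asarray(X_raw, dtype=float)
    if X.shape[1] != basis.n_voxels:
        raise ConfigurationError("voxel count does not match discovery basis")
    K_use = basis.K if K_use is None else int(K_use)
    beta_row = np.asarray(beta_row, dtype=float)
    proj = (X - basis.voxel_mean) @ basis.eigenvectors[:, :K_use]
    return proj @ beta_row[:K_use]


class ConfirmatoryTest(NamedTuple):
    t: float
    p: float
    testable: bool


def confirmatory_test(g: np.ndarray, score: np.ndarray,
                      Z: CovariateTable | np.ndarray) -> ConfirmatoryTest:
    """Covariate-adjusted marginal test between dosage and polyvoxel score.

    Both sides are residualized on the covariates; the statistic is the
    correlation t with n - p - 1 degrees of freedom, identical whichever
    variable is treated as outcome.  Returns ``testable=False`` when either
    residual has zero variance.
    """
    g = np.asarray(g, dtype=float)
    if np.any(~np.isfinite(g)):
        m = np.nanmean(g)
        g = np.where(np.isfinite(g), g, m)
    D, _ = _design(Z)
    gr = residualize(g, Z).ravel()
    sr = residualize(np.asarray(score, dtype=float), Z).ravel()
    df = len(gr) - D.shape[1] - 1
    if df <= 0:
        raise ConfigurationError("not enough subjects for the covariate design")
    vg, vs = gr @ gr, sr @ sr
    if vg <= len(gr) * 1e-14 or vs <= len(gr) * 1e-14:
        return ConfirmatoryTest(float("nan"), float("nan"), False)
    r = float((gr @ sr) / np.sqrt(vg * vs))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return ConfirmatoryTest(float("inf") if r > 0 else float("-inf"), 0.0, True)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return ConfirmatoryTest(float(t), float(p), True)


def validate_loci(loci: pd.DataFrame, X_val: PhenotypeVolumeSet,
                  G_val: GenotypeMatrix, Z_val: CovariateTable | np.ndarray,
                  basis: PCBasis, assoc: PerPCAssoc,
                  K_use: int | None = None,
                  family_alpha: float = 0.05) -> pd.DataFrame:
    """Confirmatory test for each locus lead SNP in an independent sample.

    The per-locus alpha is ``family_alpha`` divided by the number of loci
    discovered (rows of ``loci``); leads absent from the validation
    genotypes are reported untestable.
    """
    n_loci = len(loci)
    report_rows = []
    alpha = family_alpha / n_loci if n_loci else float("nan")
    for _, locus in loci.iterrows():
        lead = locus["lead_snp"]
        row: dict = {"lead_snp": lead, "chr": locus["chr"],
                     "start": locus["start"], "end": locus["end"],
                     "alpha": alpha}
        try:
            j_val = G_val.snp_index(lead)
            j_assoc = assoc.snp_row(lead)
        except KeyError:
            row.update(t=np.nan, p=np.nan, testable=False, validated=False)
            report_rows.append(row)
            continue
        score = polyvoxel_score(X_val, basis, assoc.beta[j_assoc], K_use=K_use)
        res = confirmatory_test(G_val.dosages[:, j_val], score, Z_val)
        row.update(t=res.t, p=res.p, testable=res.testable,
                   validated=bool(res.testable and res.p < alpha))
        report_rows.append(row)
    cols = ["lead_snp", "chr", "start", "end", "t", "p", "alpha",
            "testable", "validated"]
    return pd.DataFrame(report_rows, columns=cols)
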