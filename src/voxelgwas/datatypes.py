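"""Core in-memory containers shared across the pipeline stages.

Conventions
-----------
* Dosages are stored as floats in {0, 1, 2} with ``NaN`` marking missing
  calls; positions are 1-based base pairs, sorted within chromosome.
* Voxel data are stored subject-by-voxel with voxels flattened in C
  (row-major) order from the 3-D grid recorded in ``grid_dims``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a configuration or container violates its invariants."""


@dataclass
class GenotypeMatrix:
    """Subject x SNP dosage matrix with variant metadata.

    Parameters
    ----------
    dosages:
        ``(n_subjects, n_snps)`` float array; values in {0, 1, 2} or NaN.
    positions:
        1-based base-pair positions, strictly increasing within chromosome.
    chromosomes:
        Chromosome label per SNP.
    ids:
        Variant identifiers (unique).
    ref, alt:
        Allele labels; dosage counts copies of ``alt``.
    block_ids:
        Optional LD-block label per SNP (generative blocks for synthetic
        data, or labels loaded from a block BED file).
    """

    dosages: np.ndarray
    positions: np.ndarray
    chromosomes: np.ndarray
    ids: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    block_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ConfigurationError("dosages must be 2-D (subjects x SNPs)")
        m = self.dosages.shape[1]
        for name, arr in (("positions", self.positions),
                          ("chromosomes", self.chromosomes),
                          ("ids", self.ids)):
            if len(arr) != m:
                raise ConfigurationError(f"{name} length {len(arr)} != n_snps {m}")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ConfigurationError("dosage values must lie in [0, 2]")
        # positions strictly increasing within chromosome
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ConfigurationError(
                    f"positions not strictly increasing on chromosome {chrom}")
        if self.ref is None:
            self.ref = np.full(m, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(m, "G", dtype=object)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP among non-missing calls (NaN if all missing)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_fraction(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.dosages), axis=0)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        d = self.dosages.copy()
        miss = ~np.isfinite(d)
        if miss.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
            d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
        return d

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            positions=self.positions[index],
            chromosomes=self.chromosomes[index],
            ids=self.ids[index],
            ref=self.ref[index],
            alt=self.alt[index],
            block_ids=None if self.block_ids is None else self.block_ids[index],
        )

    def subset_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[np.asarray(index)],
            positions=self.positions,
            chromosomes=self.chromosomes,
            ids=self.ids,
            ref=self.ref,
            alt=self.alt,
            block_ids=self.block_ids,
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not present")
        return int(hits[0])


@dataclass
class PhenotypeVolumeSet:
    """Subject x voxel phenotype matrix for one tissue feature.

    ``values`` has voxels flattened in C order from ``grid_dims``; ``mask``
    marks voxels considered valid (inside the analysis volume).
    """

    values: np.ndarray
    grid_dims: tuple[int, int, int]
    mask: np.ndarray | None = None
    feature: str = "pheno"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        v = int(np.prod(self.grid_dims))
        if self.values.ndim != 2 or self.values.shape[1] != v:
            raise ConfigurationError(
                f"values shape {self.values.shape} incompatible with grid {self.grid_dims}")
        if self.mask is None:
            self.mask = np.ones(v, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).reshape(v)
        if not np.all(np.isfinite(self.values[:, self.mask])):
            raise ConfigurationError("non-finite phenotype values inside mask")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateTable:
    """Per-subject covariates (age, sex, global-volume analog, batch, ancestry axes).

    ``batch`` (if present) is treated as categorical and dummy-coded in the
    design matrix; all other columns enter as-is.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise ConfigurationError("covariate table contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def design_matrix(self, include: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Return an (n, p) design with intercept and dummy-coded batch.

        Reference batch level is dropped to keep the design full rank.
        """
        cols = list(self.table.columns) if include is None else list(include)
        parts = [np.ones((len(self.table), 1))]
        names = ["intercept"]
        for c in cols:
            col = self.table[c]
            if c == "batch" or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=c, drop_first=True)
                parts.append(dummies.to_numpy(dtype=float))
                names.extend(dummies.columns.tolist())
            else:
                parts.append(col.to_numpy(dtype=float)[:, None])
                names.append(c)
        return np.hstack(parts), names

    def subset(self, index: np.ndarray) -> "CovariateTable":
        return CovariateTable(self.table.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class RegionAtlas:
    """Per-region voxel probability maps P_i in [0, 1].

    ``probs`` is (n_regions, n_voxels) with voxels flattened in C order.
    """

    probs: np.ndarray
    names: list[str]
    grid_dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        v = int(np.prod(self.grid_dims))
        if self.probs.ndim != 2 or self.probs.shape[1] != v:
            raise ConfigurationError("atlas probability maps incompatible with grid")
        if len(self.names) != self.probs.shape[0]:
            raise ConfigurationError("region name count mismatch")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ConfigurationError("region probabilities must lie in [0, 1]")
        if np.any(self.probs.max(axis=1) <= 0):
            raise ConfigurationError("every region needs at least one voxel with P > 0")

    @property
    def n_regions(self) -> int:
        return self.probs.shape[0]

    def region(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            try:
                idx = self.names.index(name_or_index)
            except ValueError as exc:
                raise KeyError(f"region {name_or_index!r} not in atlas") from exc
        else:
            idx = int(name_or_index)
            if not 0 <= idx < self.n_regions:
                raise KeyError(f"region index {idx} out of range")
        return self.probs[idx]


@dataclass
class GroundTruth:
    """Generative parameters recorded by the simulator for recovery tests."""

    causal_snps: np.ndarray
    causal_regions: list[str]
    causal_betas: np.ndarray
    effect_maps: np.ndarray            # (n_causal, n_voxels): beta_q * w_qv per allele
    latent_maps: np.ndarray            # (n_latent, n_voxels)
    covariate_effects: dict[str, float]
    noise_sd: float
    avg_heritability: float            # voxel-average variance fraction from genotype

    def pc_projections(self, eigenvectors: np.ndarray) -> np.ndarray:
        """Project true effect maps onto a PC basis (n_causal x K)."""
        return self.effect_maps @ np.asarray(eigenvectors)
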