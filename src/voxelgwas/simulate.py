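"""Synthetic imaging-genetics data with known ground truth.

Emulates the statistical structure of a population imaging-genetics cohort:
biallelic genotypes in Hardy-Weinberg proportions with block LD and random
missingness, low-rank spatially smooth voxelwise phenotypes with covariate
effects, and causal SNPs whose voxel effect maps follow region probability
maps.  A discovery/validation pair of disjoint samples can be drawn from one
configuration, mirroring a temporal sample split.

The generative model for subject i, voxel v is

    y_iv = sum_c gamma_c z_ic  +  sum_q beta_q g_iq w_qv
         + sum_l u_il b_lv     +  eps_iv

with z standardized covariates (effects uniform across voxels), g dosages,
w_qv the probability map of the causal SNP's target region, b_lv smooth
latent maps with subject loadings u_il ~ N(0, latent_sd^2), and white noise
eps ~ N(0, noise_sd^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, stats

from .datatypes import (
    ConfigurationError,
    CovariateTable,
    GenotypeMatrix,
    GroundTruth,
    PhenotypeVolumeSet,
    RegionAtlas,
)

import pandas as pd

# spawn-key roles so each consumer of randomness has its own stream;
# population-level draws carry no split index and are shared across splits
_ROLE_FREQ = 0
_ROLE_GENO = 1
_ROLE_MISS = 2
_ROLE_COVAR = 3
_ROLE_PHENO = 4
_ROLE_MAPS = 5
_ROLE_ATLAS = 6


class CausalEffect(NamedTuple):
    """A causal SNP: dosage index, target region, per-allele effect (phenotype-SD units)."""

    snp: int
    region: str | int
    beta: float


@dataclass(frozen=True)
class SimConfig:
    """Data-generating knobs for one synthetic cohort."""

    n_subjects: int = 500
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    within_block_r: float = 0.5
    missing_rate: float = 0.01
    grid_dims: tuple[int, int, int] = (10, 10, 2)
    n_latent: int = 5
    latent_sd: float = 1.0
    noise_sd: float = 1.0
    noise_smoothness: float = 0.0     # sigma of optional spatially correlated noise
    causal_spec: tuple[CausalEffect, ...] = ()
    covariate_effects: tuple[tuple[str, float], ...] = (
        ("age", 0.1), ("sex", 0.1), ("volume", 0.2))
    n_ancestry_axes: int = 2
    n_batches: int = 2
    age_range: tuple[float, float] = (45.0, 80.0)
    bp_spacing: int = 10_000
    chromosome: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_snps", "ld_block_size", "n_latent"):
            if int(getattr(self, name)) <= 0 and not (name == "n_latent" and self.n_latent == 0):
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.within_block_r < 1:
            raise ConfigurationError("within_block_r must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if len(self.grid_dims) != 3 or any(int(d) <= 0 for d in self.grid_dims):
            raise ConfigurationError("grid_dims must be 3 positive integers")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        for ce in self.causal_spec:
            if not 0 <= ce.snp < self.n_snps:
                raise ConfigurationError(f"causal snp index {ce.snp} out of range")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))


def _rng(cfg_seed: int, role: int, split: int | None = None) -> np.random.Generator:
    key = (role,) if split is None else (role, split)
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=key))


def _population_freqs(cfg: SimConfig) -> np.ndarray:
    rng = _rng(cfg.seed, _ROLE_FREQ)
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, size=cfg.n_snps)


def simulate_genotypes(cfg: SimConfig, split: int = 0) -> GenotypeMatrix:
    """Draw biallelic dosages with block LD via a Gaussian copula.

    Within each block of ``ld_block_size`` SNPs the two haplotypes per
    subject are thresholded latent Gaussians with AR(1) correlation; the
    latent correlation is inflated (``sin(pi r / 2)``) so the dosage
    correlation of adjacent common SNPs approximates ``within_block_r``.
    Blocks are mutually independent.  Entries are masked missing completely
    at random at ``missing_rate``.  Deterministic given the config seed and
    split index.
    """
    freqs = _population_freqs(cfg)
    n, m = cfg.n_subjects, cfg.n_snps
    rng = _rng(cfg.seed, _ROLE_GENO, split)

    r = cfg.within_block_r
    r_latent = math.sin(math.pi * r / 2.0) if r > 0 else 0.0
    thresholds = stats.norm.ppf(freqs)  # allele present iff latent < threshold

    dosages = np.empty((n, m), dtype=float)
    block_ids = np.arange(m) // cfg.ld_block_size
    for b in np.unique(block_ids):
        idx = np.flatnonzero(block_ids == b)
        L = idx.size
        if r_latent > 0 and L > 1:
            lag = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
            chol = np.linalg.cholesky(r_latent ** lag)
        else:
            chol = np.eye(L)
        # two haplotypes per subject, independent given the block LD
        eps = rng.standard_normal(size=(2, n, L))
        latent = eps @ chol.T
        alleles = latent < thresholds[idx]
        dosages[:, idx] = alleles.sum(axis=0)

    if cfg.missing_rate > 0:
        miss = _rng(cfg.seed, _ROLE_MISS, split).random((n, m)) < cfg.missing_rate
        dosages[miss] = np.nan

    positions = 1 + np.arange(m, dtype=np.int64) * cfg.bp_spacing
    ids = np.array([f"snp{j:05d}" for j in range(m)], dtype=object)
    chroms = np.full(m, cfg.chromosome, dtype=object)
    return GenotypeMatrix(dosages=dosages, positions=positions, chromosomes=chroms,
                          ids=ids, block_ids=block_ids)


def simulate_region_atlas(grid_dims: Sequence[int], n_regions: int,
                          smoothness: float = 1.0, seed: int = 0) -> RegionAtlas:
    """Tile the grid into compact boxes, one per region, optionally smoothed.

    Boxes partition the grid (so regions are near-disjoint); with
    ``smoothness > 0`` each binary box is blurred by a Gaussian kernel of
    that sigma and rescaled to peak 1, giving soft probability blobs.  Box
    corners are jittered by at most one voxel (seeded) for variety.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    n_vox = int(np.prod(grid_dims))
    if n_regions > n_vox:
        raise ConfigurationError("more regions than voxels in the grid")
    rng = np.random.default_rng(seed)

    # split counts per axis: repeatedly split the axis with the largest
    # cell extent until enough cells exist
    splits = [1, 1, 1]
    while splits[0] * splits[1] * splits[2] < n_regions:
        extents = [grid_dims[a] / splits[a] for a in range(3)]
        candidates = [a for a in range(3) if splits[a] < grid_dims[a]]
        axis = max(candidates, key=lambda a: extents[a])
        splits[axis] += 1

    bounds = [np.linspace(0, grid_dims[a], splits[a] + 1).round().astype(int)
              for a in range(3)]
    cells = []
    for ix in range(splits[0]):
        for iy in range(splits[1]):
            for iz in range(splits[2]):
                cells.append(((bounds[0][ix], bounds[0][ix + 1]),
                              (bounds[1][iy], bounds[1][iy + 1]),
                              (bounds[2][iz], bounds[2][iz + 1])))

    probs = np.zeros((n_regions, n_vox))
    names = [f"region_{k:03d}" for k in range(n_regions)]
    for k in range(n_regions):
        box = np.zeros(grid_dims)
        slc = []
        for a, (lo, hi) in enumerate(cells[k]):
            jit = int(rng.integers(-1, 2))
            lo2 = min(max(lo + jit, 0), grid_dims[a] - 1)
            hi2 = max(min(hi + jit, grid_dims[a]), lo2 + 1)
            slc.append(slice(lo2, hi2))
        box[tuple(slc)] = 1.0
        if smoothness > 0:
            box = ndimage.gaussian_filter(box, sigma=smoothness)
            box = box / box.max()
        probs[k] = box.reshape(-1)
    return RegionAtlas(probs=probs, names=names, grid_dims=grid_dims)


def simulate_covariates(cfg: SimConfig, n: int, split: int = 0) -> CovariateTable:
    """Age, sex, global-volume analog, batch, and ancestry axes for n subjects."""
    rng = _rng(cfg.seed, _ROLE_COVAR, split)
    age = rng.uniform(*cfg.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    volume = rng.standard_normal(n)
    batch = np.array([f"b{i % cfg.n_batches}" for i in range(n)], dtype=object)
    data = {"age": age, "sex": sex, "volume": volume, "batch": batch}
    for a in range(cfg.n_ancestry_axes):
        data[f"ancestry{a + 1}"] = rng.standard_normal(n)
    return CovariateTable(pd.DataFrame(data))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _latent_maps(cfg: SimConfig) -> np.ndarray:
    """Smooth unit-RMS latent spatial maps, shared across sample splits."""
    if cfg.n_latent == 0:
        return np.zeros((0, cfg.n_voxels))
    rng = _rng(cfg.seed, _ROLE_MAPS)
    maps = np.empty((cfg.n_latent, cfg.n_voxels))
    for l in range(cfg.n_latent):
        raw = rng.standard_normal(cfg.grid_dims)
        sm = ndimage.gaussian_filter(raw, sigma=1.5)
        sm = sm / np.sqrt(np.mean(sm ** 2))
        maps[l] = sm.reshape(-1)
    return maps


def simulate_phenotypes(G: GenotypeMatrix, atlas: RegionAtlas, cfg: SimConfig,
                        split: int = 0,
                        covariates: CovariateTable | None = None,
                        ) -> tuple[PhenotypeVolumeSet, CovariateTable, GroundTruth]:
    """Generate voxelwise phenotypes from genotypes under the additive model.

    Returns the phenotype volume set, the covariate table used, and the
    exact generative parameters.  Deterministic given the config seed and
    split index.
    """
    n = G.n_subjects
    v = cfg.n_voxels
    if covariates is None:
        covariates = simulate_covariates(cfg, n, split=split)
    if covariates.n_subjects != n:
        raise ConfigurationError("covariate subject count mismatch")

    rng = _rng(cfg.seed, _ROLE_PHENO, split)
    y = np.zeros((n, v))

    gamma = dict(cfg.covariate_effects)
    for name, eff in gamma.items():
        if name not in covariates.table.columns:
            raise ConfigurationError(f"covariate {name!r} missing from table")
        z = _standardize(covariates.table[name].to_numpy(dtype=float))
        y += eff * z[:, None]

    b_maps = _latent_maps(cfg)
    if cfg.n_latent:
        u = rng.standard_normal((n, cfg.n_latent)) * cfg.latent_sd
        y += u @ b_maps

    effect_maps = np.zeros((len(cfg.causal_spec), v))
    causal_regions: list[str] = []
    dos = G.imputed_dosages()
    for q, ce in enumerate(cfg.causal_spec):
        w = atlas.region(ce.region)  # KeyError if absent
        name = ce.region if isinstance(ce.region, str) else atlas.names[int(ce.region)]
        causal_regions.append(name)
        effect_maps[q] = ce.beta * w
        y += dos[:, ce.snp][:, None] * effect_maps[q][None, :]

    if cfg.noise_sd > 0:
        eps = rng.standard_normal((n, v)) * cfg.noise_sd
        if cfg.noise_smoothness > 0:
            eps = np.stack([
                ndimage.gaussian_filter(e.reshape(cfg.grid_dims),
                                        sigma=cfg.noise_smoothness).reshape(-1)
                for e in eps])
            # rescale back to the requested marginal SD
            eps *= cfg.noise_sd / eps.std()
        y += eps

    # voxel-average fraction of variance attributable to causal dosages
    freqs = _population_freqs(cfg)
    var_g = np.zeros(v)
    for q, ce in enumerate(cfg.causal_spec):
        f = freqs[ce.snp]
        var_g += effect_maps[q] ** 2 * 2 * f * (1 - f)
    var_latent = cfg.latent_sd ** 2 * (b_maps ** 2).sum(axis=0) if cfg.n_latent else 0.0
    var_tot = var_g + var_latent + cfg.noise_sd ** 2
    avg_h2 = float(np.mean(np.divide(var_g, var_tot, out=np.zeros(v),
                                     where=var_tot > 0)))

    truth = GroundTruth(
        causal_snps=np.array([ce.snp for ce in cfg.causal_spec], dtype=int),
        causal_regions=causal_regions,
        causal_betas=np.array([ce.beta for ce in cfg.causal_spec], dtype=float),
        effect_maps=effect_maps,
        latent_maps=b_maps,
        covariate_effects=gamma,
        noise_sd=cfg.noise_sd,
        avg_heritability=avg_h2,
    )
    pheno = PhenotypeVolumeSet(values=y, grid_dims=cfg.grid_dims)
    return pheno, covariates, truth


class StudySplit(NamedTuple):
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVolumeSet
    covariates: CovariateTable


class StudyData(NamedTuple):
    discovery: StudySplit
    validation: StudySplit
    atlas: RegionAtlas
    truth: GroundTruth


def simulate_study(cfg: SimConfig, atlas: RegionAtlas | None = None,
                   n_validation: int | None = None) -> StudyData:
    """Draw disjoint discovery and validation cohorts from one configuration.

    Population-level parameters (allele frequencies, LD structure, latent
    maps, effect maps) are shared between the two splits; subject-level
    draws use distinct sub-seeds, mirroring a temporal sample split.
    """
    if atlas is None:
        atlas = simulate_region_atlas(cfg.grid_dims, n_regions=6, smoothness=1.0,
                                      seed=_rng(cfg.seed, _ROLE_ATLAS).integers(2 ** 31))
    if n_validation is None:
        n_validation = cfg.n_subjects

    g_d = simulate_genotypes(cfg, split=0)
    y_d, z_d, truth = simulate_phenotypes(g_d, atlas, cfg, split=0)

    cfg_v = replace(cfg, n_subjects=n_validation)
    g_v = simulate_genotypes(cfg_v, split=1)
    y_v, z_v, _ = simulate_phenotypes(g_v, atlas, cfg_v, split=1)

    return StudyData(discovery=StudySplit(g_d, y_d, z_d),
                     validation=StudySplit(g_v, y_v, z_v),
                     atlas=atlas, truth=truth)
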