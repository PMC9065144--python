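"""Orchestration of discovery -> validation -> enrichment runs.

A ``RunConfig`` names all inputs, thresholds, and seeds; ``run_discovery``
executes QC -> PCA -> per-PC association -> CPC -> clumping and writes
summary statistics, loci, and the PCA basis; ``run_validation`` rebuilds
polyvoxel scores from the discovery artifacts and tests every locus in an
independent sample.  Every run writes a JSON manifest with the config
hash, per-stage wall-clock, warnings, and a checksum for each output, so
re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .cpc import PCBasis, PerPCAssoc, fit_pca, per_pc_wald, run_cpc, summary_stats
from .datatypes import ConfigurationError, CovariateTable, GenotypeMatrix, PhenotypeVolumeSet
from .qc import clump_loci, variant_filters
from .polyvoxel import validate_loci


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    covariates: str
    out_dir: str
    atlas: str | None = None
    atlas_names: str | None = None
    feature: str = "pheno"
    K: int = 20
    cut_points: tuple[int, ...] = (5, 10)
    alpha: float | str = "auto"
    n_features: int = 1
    p_thresh: float | None = None       # clumping threshold; defaults to alpha
    r2_thresh: float = 0.1
    window_bp: int = 250_000
    maf_min: float = 0.005
    hwe_p_min: float = 1e-10
    miss_max: float = 0.05
    bootstrap_B: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cut_points" in raw:
            raw["cut_points"] = tuple(raw["cut_points"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cut_points"] = list(d["cut_points"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        d = asdict(self)
        d["cut_points"] = list(d["cut_points"])
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(cfg: RunConfig) -> tuple[GenotypeMatrix, PhenotypeVolumeSet, CovariateTable]:
    for name in ("genotypes", "phenotypes", "covariates"):
        p = getattr(cfg, name)
        probe = Path(p)
        # TSV-triplet genotype prefixes are checked against their variants file
        if name == "genotypes" and probe.suffix != ".vcf":
            probe = Path(f"{p}.variants.tsv")
        if not probe.exists():
            raise FileNotFoundError(f"{name} input not found: {probe}")
    G = vio.read_genotypes(cfg.genotypes)
    Y = vio.read_phenotypes(cfg.phenotypes, feature=cfg.feature)
    Z = vio.read_covariates(cfg.covariates)
    if not (G.n_subjects == Y.n_subjects == Z.n_subjects):
        raise ConfigurationError(
            f"subject counts differ: genotypes {G.n_subjects}, "
            f"phenotypes {Y.n_subjects}, covariates {Z.n_subjects}")
    return G, Y, Z


def _manifest_skeleton(cfg: RunConfig, stage: str) -> dict:
    return {"stage": stage, "config_hash": cfg.config_hash(),
            "config": {**asdict(cfg), "cut_points": list(cfg.cut_points)},
            "outputs": {}, "timings_s": {}, "warnings": []}


def _record_output(manifest: dict, key: str, path: Path) -> None:
    manifest["outputs"][key] = {"path": str(path), "sha256": vio.sha256_file(path)}


def write_basis(basis: PCBasis, out_dir: Path, assoc: PerPCAssoc | None = None) -> None:
    """Persist the discovery basis (and per-PC betas) as text tables."""
    pd.DataFrame(basis.eigenvectors,
                 columns=[f"pc{k}" for k in range(basis.K)]).to_csv(
        out_dir / "eigenvectors.tsv", sep="\t", index=False)
    pd.DataFrame({"eigenvalue": basis.eigenvalues,
                  "var_explained": basis.var_explained}).to_csv(
        out_dir / "eigenvalues.tsv", sep="\t", index=False)
    meta = {"grid_dims": list(basis.grid_dims) if basis.grid_dims else None,
            "K": basis.K}
    pd.DataFrame({"voxel_mean": basis.voxel_mean}).to_csv(
        out_dir / "voxel_mean.tsv", sep="\t", index=False)
    with open(out_dir / "basis_meta.json", "w") as fh:
        json.dump(meta, fh)
    if assoc is not None:
        pd.DataFrame(assoc.beta, index=assoc.snp_ids,
                     columns=[f"pc{k}" for k in range(assoc.K)]).to_csv(
            out_dir / "per_pc_beta.tsv", sep="\t", index_label="snp")


def read_basis(out_dir: Path) -> tuple[PCBasis, pd.DataFrame | None]:
    out_dir = Path(out_dir)
    for fname in ("eigenvectors.tsv", "eigenvalues.tsv", "voxel_mean.tsv",
                  "basis_meta.json"):
        if not (out_dir / fname).exists():
            raise FileNotFoundError(f"missing discovery artifact: {out_dir / fname}")
    V = pd.read_csv(out_dir / "eigenvectors.tsv", sep="\t").to_numpy()
    lam = pd.read_csv(out_dir / "eigenvalues.tsv", sep="\t")
    mean = pd.read_csv(out_dir / "voxel_mean.tsv", sep="\t")["voxel_mean"].to_numpy()
    with open(out_dir / "basis_meta.json") as fh:
        meta = json.load(fh)
    basis = PCBasis(eigenvectors=V, eigenvalues=lam["eigenvalue"].to_numpy(),
                    scores=np.zeros((0, V.shape[1])), voxel_mean=mean,
                    var_explained=lam["var_explained"].to_numpy(),
                    grid_dims=tuple(meta["grid_dims"]) if meta["grid_dims"] else None)
    beta_path = out_dir / "per_pc_beta.tsv"
    betas = pd.read_csv(beta_path, sep="\t", index_col="snp") if beta_path.exists() else None
    return basis, betas


def run_discovery(cfg: RunConfig) -> dict:
    """QC -> PCA -> per-PC association -> CPC -> clumping; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_skeleton(cfg, "discovery")
    stage_t0 = time.perf_counter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            G, Y, Z = _load_inputs(cfg)
            t0 = time.perf_counter()
            qc = variant_filters(G, cfg.maf_min, cfg.hwe_p_min, cfg.miss_max)
            G_kept = G.subset_snps(qc["kept"].to_numpy())
            manifest["timings_s"]["qc"] = time.perf_counter() - t0

            t0 = time.perf_counter()
            basis = fit_pca(Y, cfg.K)
            manifest["timings_s"]["pca"] = time.perf_counter() - t0

            t0 = time.perf_counter()
            assoc = per_pc_wald(basis, G_kept, Z)
            cpc = run_cpc(assoc, cut_points=cfg.cut_points, alpha=cfg.alpha,
                          n_features=cfg.n_features)
            ss = summary_stats(cpc, G_kept, feature=cfg.feature)
            manifest["timings_s"]["association"] = time.perf_counter() - t0

            t0 = time.perf_counter()
            p_thresh = cfg.p_thresh if cfg.p_thresh is not None else cpc.alpha
            loci = clump_loci(ss, G_kept, p_thresh=p_thresh,
                              r2_thresh=cfg.r2_thresh, window_bp=cfg.window_bp)
            manifest["timings_s"]["clumping"] = time.perf_counter() - t0

            vio.write_table(qc, out / "qc_report.tsv")
            vio.write_table(ss, out / "summary_stats.tsv")
            vio.write_table(cpc.table, out / "cpc_full.tsv")
            vio.write_table(loci, out / "loci.tsv")
            write_basis(basis, out, assoc)
            for key in ("qc_report.tsv", "summary_stats.tsv", "cpc_full.tsv",
                        "loci.tsv", "eigenvectors.tsv", "eigenvalues.tsv",
                        "voxel_mean.tsv", "per_pc_beta.tsv", "basis_meta.json"):
                _record_output(manifest, key, out / key)
            manifest["alpha"] = cpc.alpha
            manifest["n_significant"] = cpc.n_significant
            manifest["n_loci"] = len(loci)
            manifest["warnings"] = [str(w.message) for w in caught]
            manifest["status"] = "ok"
    except Exception as exc:  # record the failing stage, keep partial outputs
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        vio.write_manifest(manifest, out / "manifest.json")
        raise
    manifest["timings_s"]["total"] = time.perf_counter() - stage_t0
    vio.write_manifest(manifest, out / "manifest.json")
    return manifest


def run_validation(cfg: RunConfig, discovery_dir: str | Path) -> dict:
    """Confirmatory polyvoxel-score tests for the discovered loci."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    discovery_dir = Path(discovery_dir)
    manifest = _manifest_skeleton(cfg, "validation")
    t_all = time.perf_counter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            basis, betas = read_basis(discovery_dir)
            loci_path = discovery_dir / "loci.tsv"
            if not loci_path.exists():
                raise FileNotFoundError(f"missing discovery artifact: {loci_path}")
            loci = vio.read_table(loci_path, list_cols=("members", "member_ps", "features"))
            if betas is None:
                raise FileNotFoundError(
                    f"missing discovery artifact: {discovery_dir / 'per_pc_beta.tsv'}")
            G, Y, Z = _load_inputs(cfg)

            disc_manifest_path = discovery_dir / "manifest.json"
            if disc_manifest_path.exists():
                disc = vio.read_manifest(disc_manifest_path)
                if disc.get("config", {}).get("genotypes") == cfg.genotypes:
                    warnings.warn("validation sample appears identical to the "
                                  "discovery sample; tests are not independent")

            assoc = PerPCAssoc(beta=betas.to_numpy(), se=np.full(betas.shape, np.nan),
                               wald=np.full(betas.shape, np.nan),
                               snp_ids=betas.index.to_numpy(dtype=object),
                               df_resid=0, tested=np.ones(len(betas), dtype=bool))
            report = validate_loci(loci, Y, G, Z, basis, assoc)
            vio.write_table(report, out / "validation_report.tsv")
            _record_output(manifest, "validation_report.tsv", out / "validation_report.tsv")
            manifest["n_loci"] = len(report)
            manifest["n_validated"] = int(report["validated"].sum()) if len(report) else 0
            manifest["warnings"] = [str(w.message) for w in caught]
            manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        vio.write_manifest(manifest, out / "manifest.json")
        raise
    manifest["timings_s"]["total"] = time.perf_counter() - t_all
    vio.write_manifest(manifest, out / "manifest.json")
    return manifest
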