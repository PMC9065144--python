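"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT field, uncompressed text) or as a PLINK-style
TSV triplet (variants / samples / dosages); phenotypes and atlases as
NIfTI volumes (subject or region on the 4th axis) or dense TSV; tables as
TSV.  Voxel flattening is C (row-major) order, matching the in-memory
containers.  Base-pair positions are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import CovariateTable, GenotypeMatrix, PhenotypeVolumeSet, RegionAtlas

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


# ---------------------------------------------------------------- genotypes

def write_vcf(G: GenotypeMatrix, path: str | Path,
              sample_ids: list[str] | None = None) -> None:
    path = Path(path)
    n = G.n_subjects
    samples = sample_ids or [f"S{i:05d}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=voxelgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.chromosomes):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(G.n_snps):
            gts = []
            for i in range(n):
                d = G.dosages[i, j]
                gts.append("./." if not np.isfinite(d) else _GT_CODES[int(round(d))])
            fh.write(f"{G.chromosomes[j]}\t{G.positions[j]}\t{G.ids[j]}\t"
                     f"{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain-text) VCF with GT calls into a dosage matrix."""
    path = Path(path)
    ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            parts = line.rstrip("\n").split("\t")
            chroms.append(parts[0])
            pos.append(int(parts[1]))
            ids.append(parts[2])
            ref.append(parts[3])
            alt.append(parts[4])
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            row = []
            for cell in parts[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) for a in gt.split("/"))))
            rows.append(row)
    dosages = np.asarray(rows, dtype=float).T
    return GenotypeMatrix(dosages=dosages, positions=np.asarray(pos),
                          chromosomes=np.asarray(chroms, dtype=object),
                          ids=np.asarray(ids, dtype=object),
                          ref=np.asarray(ref, dtype=object),
                          alt=np.asarray(alt, dtype=object))


def write_genotypes_tsv(G: GenotypeMatrix, prefix: str | Path,
                        sample_ids: list[str] | None = None) -> None:
    """PLINK-style text triplet: <prefix>.variants.tsv / .samples.tsv / .dosages.tsv."""
    prefix = Path(prefix)
    var = pd.DataFrame({"snp": G.ids, "chr": G.chromosomes, "pos": G.positions,
                        "a1": G.ref, "a2": G.alt})
    if G.block_ids is not None:
        var["block"] = G.block_ids
    var.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    samples = sample_ids or [f"S{i:05d}" for i in range(G.n_subjects)]
    pd.DataFrame({"sample": samples}).to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)
    pd.DataFrame(G.dosages, columns=G.ids).to_csv(
        f"{prefix}.dosages.tsv", sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    var = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", na_values="NA")
    return GenotypeMatrix(
        dosages=dos.to_numpy(dtype=float),
        positions=var["pos"].to_numpy(),
        chromosomes=var["chr"].astype(str).to_numpy(dtype=object),
        ids=var["snp"].to_numpy(dtype=object),
        ref=var["a1"].to_numpy(dtype=object),
        alt=var["a2"].to_numpy(dtype=object),
        block_ids=var["block"].to_numpy() if "block" in var else None,
    )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf or a TSV-triplet prefix."""
    p = Path(path)
    if p.suffix == ".vcf":
        return read_vcf(p)
    return read_genotypes_tsv(p)


# --------------------------------------------------------------- phenotypes

def write_phenotypes_nifti(Y: PhenotypeVolumeSet, path: str | Path) -> None:
    """4-D NIfTI with subject on the 4th axis; grid dims in the header."""
    arr = Y.values.T.reshape(*Y.grid_dims, Y.n_subjects).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def read_phenotypes_nifti(path: str | Path, feature: str = "pheno") -> PhenotypeVolumeSet:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    grid = arr.shape[:3]
    values = arr.reshape(int(np.prod(grid)), arr.shape[3]).T
    return PhenotypeVolumeSet(values=values, grid_dims=grid, feature=feature)


def write_phenotypes_tsv(Y: PhenotypeVolumeSet, path: str | Path) -> None:
    df = pd.DataFrame(Y.values, columns=[f"v{j}" for j in range(Y.n_voxels)])
    with open(path, "w") as fh:
        fh.write(f"#grid_dims={Y.grid_dims[0]},{Y.grid_dims[1]},{Y.grid_dims[2]}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path, feature: str = "pheno") -> PhenotypeVolumeSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#grid_dims="):
            raise ValueError(f"{path}: missing #grid_dims header")
        grid = tuple(int(x) for x in header.strip().split("=")[1].split(","))
        df = pd.read_csv(fh, sep="\t")
    return PhenotypeVolumeSet(values=df.to_numpy(dtype=float), grid_dims=grid,
                              feature=feature)


def read_phenotypes(path: str | Path, feature: str = "pheno") -> PhenotypeVolumeSet:
    p = Path(path)
    if p.suffix in (".nii", ".gz"):
        return read_phenotypes_nifti(p, feature)
    return read_phenotypes_tsv(p, feature)


# -------------------------------------------------------------------- atlas

def write_atlas_nifti(atlas: RegionAtlas, path: str | Path,
                      names_path: str | Path | None = None) -> None:
    arr = atlas.probs.T.reshape(*atlas.grid_dims, atlas.n_regions).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
    if names_path is not None:
        pd.DataFrame({"index": range(atlas.n_regions),
                      "region": atlas.names}).to_csv(names_path, sep="\t", index=False)


def read_atlas_nifti(path: str | Path, names_path: str | Path | None = None) -> RegionAtlas:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    grid = arr.shape[:3]
    probs = arr.reshape(int(np.prod(grid)), arr.shape[3]).T
    if names_path is not None:
        names = pd.read_csv(names_path, sep="\t")["region"].tolist()
    else:
        names = [f"region_{k:03d}" for k in range(probs.shape[0])]
    return RegionAtlas(probs=probs, names=names, grid_dims=grid)


# ------------------------------------------------------------------- tables

def write_covariates(Z: CovariateTable, path: str | Path) -> None:
    Z.table.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t"))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV, flattening list-valued columns."""
    out = df.copy()
    for col in out.columns:
        if len(out) and isinstance(out[col].iloc[0], (list, tuple)):
            out[col] = out[col].map(lambda xs: ",".join(str(x) for x in xs))
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, list_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in list_cols:
        if col in df:
            df[col] = df[col].map(
                lambda s: [] if pd.isna(s) or s == "" else str(s).split(","))
    return df


def read_bed_blocks(path: str | Path) -> pd.DataFrame:
    """LD-block definitions from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chr", "start", "end"], usecols=[0, 1, 2])
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["block"] = np.arange(len(df))
    return df


def assign_blocks(G: GenotypeMatrix, blocks: pd.DataFrame) -> np.ndarray:
    """Map each SNP to the (first) block whose interval contains its position."""
    out = np.full(G.n_snps, -1, dtype=int)
    for _, row in blocks.iterrows():
        hit = ((G.chromosomes == str(row["chr"]))
               & (G.positions >= row["start"]) & (G.positions <= row["end"]))
        out[hit & (out < 0)] = int(row["block"])
    return out


# ----------------------------------------------------------------- manifest

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
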