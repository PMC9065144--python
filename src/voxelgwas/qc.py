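"""Variant quality control, LD, significance-based clumping, and locus merging.

QC keeps common well-called variants in Hardy-Weinberg equilibrium:
minor allele frequency >= 0.5%, HWE chi-square p >= 1e-10, and call
missingness <= 5% by default.  Significant SNPs are clumped greedily
around lead SNPs: a SNP joins the current lead's locus if it is either in
LD with the lead (r^2 above threshold) or physically close to it (within
the clumping window); loci from different features whose genomic ranges
overlap are merged into unique loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix

DEFAULT_MAF_MIN = 0.005
DEFAULT_HWE_P_MIN = 1e-10
DEFAULT_MISS_MAX = 0.05
DEFAULT_R2_THRESH = 0.1
DEFAULT_WINDOW_BP = 250_000


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square Hardy-Weinberg test p-value from genotype counts.

    Counts are (hom-ref, het, hom-alt) among non-missing subjects; no
    continuity correction.  Monomorphic counts are untestable and return 1.
    """
    n = n0 + n1 + n2
    if n == 0:
        return float("nan")
    p = (n1 + 2 * n2) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([n * q * q, n * 2 * p * q, n * p * p])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def variant_filters(G: GenotypeMatrix,
                    maf_min: float = DEFAULT_MAF_MIN,
                    hwe_p_min: float = DEFAULT_HWE_P_MIN,
                    miss_max: float = DEFAULT_MISS_MAX) -> pd.DataFrame:
    """Per-SNP QC report with kept flag and failure reason.

    A SNP is kept iff MAF >= maf_min AND HWE p >= hwe_p_min AND missing
    fraction <= miss_max.  A SNP with all calls missing fails missingness
    (MAF and HWE are then undefined and reported as NaN).
    """
    maf = G.minor_allele_freq()
    miss = G.missing_fraction()
    hwe = np.empty(G.n_snps)
    for j in range(G.n_snps):
        d = G.dosages[:, j]
        d = d[np.isfinite(d)]
        counts = np.bincount(np.rint(d).astype(int), minlength=3)[:3]
        hwe[j] = hwe_chi2_p(*counts)

    with np.errstate(invalid="ignore"):
        pass_maf = maf >= maf_min
        pass_hwe = hwe >= hwe_p_min
    pass_miss = miss <= miss_max
    # undefined MAF/HWE (all-missing SNP) does not count as a pass
    pass_maf &= np.isfinite(maf)
    pass_hwe &= np.isfinite(hwe)
    kept = pass_maf & pass_hwe & pass_miss

    reasons = []
    for j in range(G.n_snps):
        fails = []
        if not pass_miss[j]:
            fails.append("missingness")
        if not pass_maf[j] and np.isfinite(maf[j]):
            fails.append("maf")
        if not pass_hwe[j] and np.isfinite(hwe[j]):
            fails.append("hwe")
        reasons.append(";".join(fails))
    return pd.DataFrame({
        "snp": G.ids, "maf": maf, "hwe_p": hwe, "missing_frac": miss,
        "kept": kept, "reason": reasons,
    })


def ld_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson dosage correlation over pairwise-complete subjects.

    Returns NaN if fewer than two complete pairs remain or either SNP has
    zero variance after removing missing calls.
    """
    x = G.dosages[:, i]
    y = G.dosages[:, j]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_matrix(G: GenotypeMatrix, index: np.ndarray | None = None) -> np.ndarray:
    """Pairwise r^2 matrix on mean-imputed dosages (fast path for many SNPs)."""
    d = G.imputed_dosages()
    if index is not None:
        d = d[:, np.asarray(index)]
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = np.nan
    d = d / sd
    r = (d.T @ d) / d.shape[0]
    return r ** 2


def clump_loci(ss: pd.DataFrame, G: GenotypeMatrix,
               p_thresh: float = 4.2e-9,
               r2_thresh: float = DEFAULT_R2_THRESH,
               window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Greedy significance clumping of summary statistics into loci.

    ``ss`` needs columns ``snp, chr, pos, p`` (optionally ``feature``).
    Repeatedly the unassigned significant SNP with the smallest p (ties
    broken by position, then id) becomes a lead; every unassigned
    significant SNP on the same chromosome with r^2 > ``r2_thresh`` to the
    lead OR within ``window_bp`` of it joins the lead's locus.  The locus
    span is the min/max member position.  Returns one row per locus.
    """
    sig = ss[ss["p"] < p_thresh].copy()
    if sig.empty:
        return _empty_locus_table()
    sig = sig.sort_values(["p", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    snp_col = {sid: G.snp_index(sid) for sid in sig["snp"]}
    assigned = np.zeros(len(sig), dtype=bool)
    rows = []
    while not assigned.all():
        lead_row = int(np.flatnonzero(~assigned)[0])
        lead = sig.iloc[lead_row]
        same_chr = (sig["chr"].to_numpy() == lead["chr"]) & ~assigned
        cand = np.flatnonzero(same_chr)
        members = [lead_row]
        for k in cand:
            if k == lead_row:
                continue
            close = abs(int(sig.iloc[k]["pos"]) - int(lead["pos"])) <= window_bp
            if close:
                members.append(int(k))
                continue
            r2 = ld_r2(G, snp_col[lead["snp"]], snp_col[sig.iloc[k]["snp"]])
            if np.isfinite(r2) and r2 > r2_thresh:
                members.append(int(k))
        assigned[members] = True
        mem = sig.iloc[members]
        features = sorted(set(mem["feature"])) if "feature" in mem else []
        rows.append({
            "chr": lead["chr"],
            "start": int(mem["pos"].min()),
            "end": int(mem["pos"].max()),
            "lead_snp": lead["snp"],
            "lead_pos": int(lead["pos"]),
            "min_p": float(lead["p"]),
            "n_members": len(members),
            "members": list(mem["snp"]),
            "member_ps": [float(x) for x in mem["p"]],
            "features": features,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["chr", "start"], kind="mergesort").reset_index(drop=True)


def _empty_locus_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["chr", "start", "end", "lead_snp", "lead_pos",
                                 "min_p", "n_members", "members", "member_ps",
                                 "features"])


def merge_unique_loci(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Union loci whose [start, end] ranges overlap on the same chromosome.

    Feature provenance accumulates; the merged lead is the member with the
    smallest p across the merged loci.
    """
    frames = [t for t in tables if len(t)]
    if not frames:
        return _empty_locus_table()
    allloci = pd.concat(frames, ignore_index=True)
    allloci = allloci.sort_values(["chr", "start", "end"], kind="mergesort")
    rows = []
    current = None
    for _, row in allloci.iterrows():
        if current is not None and row["chr"] == current["chr"] and row["start"] <= current["end"]:
            current["end"] = max(current["end"], int(row["end"]))
            current["members"] = list(dict.fromkeys(current["members"] + list(row["members"])))
            current["member_ps"] = current["member_ps"] + list(row["member_ps"])
            current["features"] = sorted(set(current["features"]) | set(row["features"]))
            if row["min_p"] < current["min_p"]:
                current["min_p"] = float(row["min_p"])
                current["lead_snp"] = row["lead_snp"]
                current["lead_pos"] = int(row["lead_pos"])
            current["n_members"] = len(current["members"])
        else:
            if current is not None:
                rows.append(current)
            current = {k: (list(row[k]) if isinstance(row[k], (list, tuple)) else row[k])
                       for k in allloci.columns}
            current["start"] = int(row["start"])
            current["end"] = int(row["end"])
        # fallthrough
    if current is not None:
        rows.append(current)
    return pd.DataFrame(rows).reset_index(drop=True)
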