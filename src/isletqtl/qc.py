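"""Variant- and sample-level quality control.

Two-stage variant filtering mirrors a genotype-then-impute design: call rate,
pre-imputation MAF and Hardy-Weinberg equilibrium apply only to directly
genotyped variants, whereas the imputation INFO score and the analysis MAF
apply to every variant entering the eQTL scan.  Surviving missing dosages are
mean-imputed, which leaves each variant's allele frequency unchanged.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import ExonCountMatrix, GenotypeMatrix


def compute_maf(dosages: np.ndarray) -> float:
    """Folded minor-allele frequency of a dosage vector (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("cannot compute MAF: all dosages missing")
    f_alt = float(d[ok].sum()) / (2.0 * n)
    return min(f_alt, 1.0 - f_alt)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test on genotype class counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no
    more likely than the observed one (the standard exact-test convention).
    Returns 1.0 for monomorphic variants.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotype calls")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    if n_rare == 0:
        return 1.0

    # P(het = h | n, n_rare) proportional to n! / (n_aa! n_ab! n_bb!) * 2^h
    # computed in log space over all h with the parity of n_rare.
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = np.empty(hets.shape)
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = (
            h * math.log(2.0)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(common_hom + 1)
        )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_het)[0]]
    # tolerance guards against float noise when summing "<= observed"
    return float(min(1.0, prob[prob <= obs * (1.0 + 1e-12)].sum()))


def hwe_from_dosages(dosages: np.ndarray) -> float:
    """HWE exact p from dosages, rounded to hard genotype calls."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    calls = np.clip(np.rint(d), 0, 2).astype(int)
    return hwe_exact_test(
        int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum())
    )


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (in place on a copy)."""
    d = np.array(dosages, dtype=float, copy=True)
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = np.isnan(col)
        if miss.any():
            col[miss] = np.nanmean(col)
    return d


def filter_variants(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.99,
    pre_imputation_maf: float = 0.01,
    hwe_alpha: float = 1e-4,
    min_info: float = 0.4,
    analysis_maf: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply two-stage variant QC; returns the filtered matrix and a report.

    Genotyped variants (``variants.genotyped``) must pass call rate,
    pre-imputation MAF and HWE; all variants must pass INFO and the analysis
    MAF. Missing dosages of surviving variants are mean-imputed.
    """
    n_v = gm.n_variants
    genotyped = gm.variants["genotyped"].to_numpy(dtype=bool)
    info = gm.variants["info"].to_numpy(dtype=float)
    info = np.where(np.isnan(info), 1.0, info)

    call_rate = 1.0 - np.isnan(gm.dosages).mean(axis=0)
    maf = np.array([compute_maf(gm.dosages[:, j]) for j in range(n_v)])
    hwe_p = np.full(n_v, np.nan)
    for j in np.flatnonzero(genotyped):
        hwe_p[j] = hwe_from_dosages(gm.dosages[:, j])

    pass_call = ~genotyped | (call_rate >= min_call_rate)
    pass_premaf = ~genotyped | (maf >= pre_imputation_maf)
    pass_hwe = ~genotyped | (hwe_p >= hwe_alpha)
    pass_info = info > min_info
    pass_amaf = maf > analysis_maf
    keep = pass_call & pass_premaf & pass_hwe & pass_info & pass_amaf

    report = pd.DataFrame(
        {
            "variant_id": gm.variants["variant_id"],
            "genotyped": genotyped,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "info": info,
            "pass_call_rate": pass_call,
            "pass_pre_imputation_maf": pass_premaf,
            "pass_hwe": pass_hwe,
            "pass_info": pass_info,
            "pass_analysis_maf": pass_amaf,
            "kept": keep,
        }
    )

    if not keep.any():
        attrition = {
            "call_rate": int((~pass_call).sum()),
            "pre_imputation_maf": int((~pass_premaf).sum()),
            "hwe": int((~pass_hwe).sum()),
            "info": int((~pass_info).sum()),
            "analysis_maf": int((~pass_amaf).sum()),
        }
        raise ValueError(f"no variants survive QC; per-filter failures: {attrition}")

    out = gm.subset_variants(keep)
    out.dosages = mean_impute(out.dosages)
    return out, report


def filter_samples(
    counts: ExonCountMatrix, min_mapped_reads: int = 10_000_000
) -> list[str]:
    """Samples whose total exon-mapped reads reach the sequencing-depth floor."""
    totals = counts.sample_totals()
    return [s for s, t in zip(counts.samples, totals) if t >= min_mapped_reads]
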