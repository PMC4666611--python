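"""GWAS effector-transcript nomination cascade.

For each GWAS locus and each gene whose TSS lies within 1 Mb of the lead
variant, the gene's best exon (smallest empirical p) must

1. reach a significance tier: study-wide (q < 0.05) or nominal
   (empirical p < 0.05);
2. have its eQTL index variant in strong LD with the GWAS lead (r^2 > 0.8);
3. lose its signal when the lead variant is regressed out (conditional
   p > alpha, the colocalization rule; an alternative >= 90% drop in
   -log10 p rule is reported alongside);
4. have the index variant, or a strong-LD proxy of it, overlap an active
   (enhancer/promoter) chromatin state.

Surviving calls carry the risk-allele expression direction and the gene's
directional consistency across exons ("23/24"-style strings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import overlap_variants
from .cis import covariate_basis
from .core import ChromatinAnnotation, ExpressionMatrix, GenotypeMatrix, GwasLocus

ACTIVE_STATES = frozenset({"enhancer", "promoter"})
COLLINEAR_R2 = 0.999


def compute_ld_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dosage vector has undefined LD")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ConditionalResult:
    conditional_p: float
    conditional_beta: float
    collinear: bool


def conditional_test(
    y: np.ndarray,
    g_eqtl: np.ndarray,
    g_lead: np.ndarray,
    C: np.ndarray | pd.DataFrame | None = None,
) -> ConditionalResult:
    """t-test on the eQTL dosage after adding the GWAS lead as a covariate.

    When the two dosages are collinear beyond r^2 > 0.999 the lead absorbs
    the signal entirely by construction; conditional p = 1 with a flag.
    """
    y = np.asarray(y, dtype=float)
    ge = np.asarray(g_eqtl, dtype=float)
    gl = np.asarray(g_lead, dtype=float)
    if compute_ld_r2(ge, gl) > COLLINEAR_R2:
        return ConditionalResult(conditional_p=1.0, conditional_beta=0.0, collinear=True)
    n = y.size
    Q = covariate_basis(C, n)  # raises on rank-deficient C
    X = np.column_stack([np.ones(n), ge, gl]) if C is None else np.column_stack(
        [np.ones(n), ge, gl, np.asarray(C, dtype=float)]
    )
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("not enough samples for the conditional model")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("conditional design matrix is rank deficient")
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = coef[1] / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ConditionalResult(conditional_p=p, conditional_beta=float(coef[1]), collinear=False)


def directional_consistency(
    gene_pairs: pd.DataFrame, index_exon_id: str
) -> tuple[int, int]:
    """Count exons whose beta at the index variant matches the index exon's sign.

    ``gene_pairs`` holds one row per exon of the gene with a ``beta`` column
    measured at the gene's index variant; the count includes the index exon.
    """
    betas = gene_pairs["beta"].to_numpy(dtype=float)
    exon_ids = gene_pairs["exon_id"].astype(str).to_numpy()
    hits = np.flatnonzero(exon_ids == str(index_exon_id))
    if hits.size == 0:
        raise ValueError(f"index exon {index_exon_id!r} not in gene pair table")
    ref_sign = np.sign(betas[hits[0]])
    n_total = betas.size
    n_consistent = int((np.sign(betas) == ref_sign).sum())
    return n_consistent, n_total


def consistency_string(n_consistent: int, n_total: int) -> str:
    return f"{n_consistent}/{n_total}"


def _betas_at_variant(
    expr: ExpressionMatrix,
    gm: GenotypeMatrix,
    gene_id: str,
    variant_id: str,
    Q: np.ndarray,
) -> pd.DataFrame:
    """Per-exon beta of a gene's exons at one variant (covariate-adjusted)."""
    g = gm.dosage(variant_id)
    gr = g - Q @ (Q.T @ g)
    gss = float(gr @ gr)
    rows = []
    gene_mask = expr.exons["gene_id"].astype(str) == str(gene_id)
    for i in np.flatnonzero(gene_mask.to_numpy()):
        y = expr.values[i]
        yr = y - Q @ (Q.T @ y)
        rows.append(
            {"exon_id": expr.exons.iloc[i]["exon_id"], "beta": float(yr @ gr) / gss}
        )
    return pd.DataFrame(rows)


def _chromatin_gate(
    gm: GenotypeMatrix,
    index_variant: str,
    annotation: ChromatinAnnotation,
    r2_min: float,
    states: frozenset[str] = ACTIVE_STATES,
) -> tuple[bool, bool]:
    """(index variant overlaps active state, index-or-proxy overlaps)."""
    j = gm.index_of(index_variant)
    g_index = gm.dosages[:, j]
    same_chrom = (
        gm.variants["chrom"].astype(str) == str(gm.variants.iloc[j]["chrom"])
    ).to_numpy()
    proxy_idx = [j]
    for k in np.flatnonzero(same_chrom):
        if k == j or np.ptp(gm.dosages[:, k]) == 0:
            continue
        if compute_ld_r2(g_index, gm.dosages[:, k]) > r2_min:
            proxy_idx.append(int(k))
    sub = gm.variants.iloc[proxy_idx]
    flags = overlap_variants(
        sub["chrom"].astype(str).to_numpy(),
        sub["pos"].to_numpy(int),
        annotation,
        states=states,
    )
    return bool(flags[0]), bool(flags.any())


def nominate_effectors(
    fdr: pd.DataFrame,
    gwas_loci: list[GwasLocus],
    gm: GenotypeMatrix,
    expr: ExpressionMatrix,
    C: np.ndarray | pd.DataFrame | None,
    annotation: ChromatinAnnotation,
    r2_min: float = 0.8,
    coloc_alpha: float = 0.05,
    q_threshold: float = 0.05,
    nominal_threshold: float = 0.05,
    flank: int = 1_000_000,
    require_chromatin: bool = True,
) -> pd.DataFrame:
    """Run the nomination cascade; one row per surviving locus x gene call."""
    n = len(expr.samples)
    Q = covariate_basis(C, n)
    tested = fdr[fdr["empirical_p"].notna()]
    calls = []
    for locus in gwas_loci:
        try:
            j_lead = gm.index_of(locus.variant_id)
        except KeyError:
            import warnings

            warnings.warn(
                f"GWAS lead {locus.variant_id} absent from genotypes; "
                f"locus {locus.locus} skipped",
                stacklevel=2,
            )
            continue
        g_lead = gm.dosages[:, j_lead]
        lead_alt = str(gm.variants.iloc[j_lead]["alt"])
        near = tested[
            (tested["chrom"].astype(str) == str(locus.chrom))
            & ((tested["tss"] - locus.pos).abs() <= flank)
        ]
        for gene_id, gene_rows in near.groupby("gene_id", sort=True):
            # best exon per locus x gene: smallest empirical p, ties by q then
            # genomic order of the exon
            best = gene_rows.sort_values(
                ["empirical_p", "q", "tss"], kind="stable"
            ).iloc[0]
            if best["q"] < q_threshold:
                tier = "study_wide"
            elif best["empirical_p"] < nominal_threshold:
                tier = "nominal"
            else:
                continue
            index_variant = best["index_variant"]
            g_index = gm.dosage(index_variant)
            r2 = compute_ld_r2(g_index, g_lead)
            if r2 <= r2_min:
                continue
            i_exon = int(
                np.flatnonzero(
                    expr.exons["exon_id"].astype(str).to_numpy()
                    == str(best["exon_id"])
                )[0]
            )
            cond = conditional_test(expr.values[i_exon], g_index, g_lead, C)
            marginal_p = float(best["min_p"])
            if cond.conditional_p > 0:
                drop = 1.0 - np.log10(cond.conditional_p) / np.log10(marginal_p)
            else:
                drop = 0.0
            if cond.conditional_p <= coloc_alpha:
                continue
            idx_overlap, proxy_overlap = _chromatin_gate(
                gm, index_variant, annotation, r2_min
            )
            if require_chromatin and not proxy_overlap:
                continue
            pair_betas = _betas_at_variant(expr, gm, gene_id, index_variant, Q)
            n_cons, n_tot = directional_consistency(pair_betas, best["exon_id"])
            # orient expression effect to the risk allele (beta is per alt dose)
            beta_alt = float(best["beta"])
            beta_risk = beta_alt if locus.risk_allele == lead_alt else -beta_alt
            calls.append(
                {
                    "locus": locus.locus,
                    "trait": locus.trait,
                    "lead_variant": locus.variant_id,
                    "gene_id": gene_id,
                    "exon_id": best["exon_id"],
                    "index_variant": index_variant,
                    "r2_with_lead": r2,
                    "empirical_p": float(best["empirical_p"]),
                    "q": float(best["q"]),
                    "tier": tier,
                    "marginal_p": marginal_p,
                    "conditional_p": cond.conditional_p,
                    "conditional_beta": cond.conditional_beta,
                    "collinear_with_lead": cond.collinear,
                    "log10p_drop_fraction": drop,
                    "chromatin_overlap_index": idx_overlap,
                    "chromatin_overlap_proxy": proxy_overlap,
                    "risk_allele": locus.risk_allele,
                    "beta_risk_allele": beta_risk,
                    "direction": "up" if beta_risk > 0 else "down",
                    "directional_consistency": consistency_string(n_cons, n_tot),
                    "n_consistent": n_cons,
                    "n_exons": n_tot,
                }
            )
    columns = [
        "locus", "trait", "lead_variant", "gene_id", "exon_id", "index_variant",
        "r2_with_lead", "empirical_p", "q", "tier", "marginal_p", "conditional_p",
        "conditional_beta", "collinear_with_lead", "log10p_drop_fraction",
        "chromatin_overlap_index", "chromatin_overlap_proxy", "risk_allele",
        "beta_risk_allele", "direction", "directional_consistency",
        "n_consistent", "n_exons",
    ]
    return pd.DataFrame(calls, columns=columns)
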