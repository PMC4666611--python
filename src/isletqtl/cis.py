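"""Additive-model cis scan: every variant within +/-1 Mb of a gene's TSS is
regressed against each exon phenotype, adjusting for covariates, and the
variant with the smallest p-value becomes the exon's index variant.

The per-window fit is ordinary least squares of y on [1, g, C].  For speed the
covariates (plus intercept) are projected out of both phenotype and dosages
once per exon (Frisch-Waugh), after which every variant's beta, SE, t and
two-sided p come from vectorized partial regressions; this is numerically
identical to the full OLS fit and is cross-checked against it in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CisAssociation, ExpressionMatrix, GenotypeMatrix

CIS_FLANK_BP = 1_000_000


def define_cis_window(tss: int, flank: int = CIS_FLANK_BP) -> tuple[int, int]:
    """Closed 1-based interval [max(1, tss - flank), tss + flank]."""
    if tss < 1:
        raise ValueError("TSS positions are 1-based")
    return max(1, tss - flank), tss + flank


def covariate_basis(C: np.ndarray | pd.DataFrame | None, n: int) -> np.ndarray:
    """Orthonormal basis of the span of [1, C] (n x q, q >= 1).

    Raises if the covariate matrix is rank deficient after adding the
    intercept (constant covariate columns count as rank deficiency).
    """
    if C is None:
        cols = np.ones((n, 1))
    else:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols = np.column_stack([np.ones(n), C])
    q, r = np.linalg.qr(cols)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * max(1.0, diag.max())).any():
        raise ValueError("covariate matrix is rank deficient (with intercept)")
    return q


def _partial_stats(
    y_resid: np.ndarray, G_resid: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """beta, se, t, p for each column of residualized dosages vs phenotype."""
    gss = np.einsum("ij,ij->j", G_resid, G_resid)
    ok = gss > 1e-12
    num = y_resid @ G_resid
    yss = float(y_resid @ y_resid)
    beta = np.full(gss.shape, np.nan)
    se = np.full(gss.shape, np.nan)
    beta[ok] = num[ok] / gss[ok]
    rss = np.maximum(yss - beta[ok] * num[ok], 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / gss[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    return beta, se, t, p


def fit_additive_model(
    y: np.ndarray,
    g: np.ndarray,
    C: np.ndarray | pd.DataFrame | None = None,
    exon_id: str = "",
    variant_id: str = "",
) -> CisAssociation:
    """OLS of y on [1, g, C] with a two-sided t-test on the dosage term."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    Q = covariate_basis(C, n)
    df = n - Q.shape[1] - 1
    if df <= 0:
        raise ValueError(f"not enough samples (n={n}) for {Q.shape[1]} covariates")
    if np.ptp(g) == 0:
        raise ValueError("constant dosage vector: variant not testable")
    yr = y - Q @ (Q.T @ y)
    gr = g - Q @ (Q.T @ g)
    beta, se, t, p = _partial_stats(yr, gr[:, None], df)
    return CisAssociation(
        exon_id=exon_id,
        variant_id=variant_id,
        beta=float(beta[0]),
        se=float(se[0]),
        t_stat=float(t[0]),
        p=float(p[0]),
        n=n,
    )


@dataclass
class CisScanResult:
    """Per-exon index-variant summary plus (optionally) the pair-level table."""

    table: pd.DataFrame  # one row per exon
    pairs: pd.DataFrame | None = None


def _window_variant_indices(
    gm: GenotypeMatrix, chrom: str, lo: int, hi: int
) -> np.ndarray:
    v = gm.variants
    mask = (v["chrom"].astype(str) == str(chrom)) & (v["pos"] >= lo) & (v["pos"] <= hi)
    return np.flatnonzero(mask.to_numpy())


def _pick_index(p: np.ndarray, t: np.ndarray, pos: np.ndarray) -> int:
    """Smallest p; ties by larger |t|, then smaller genomic position."""
    ok = ~np.isnan(p)
    cand = np.flatnonzero(ok)
    order = np.lexsort((pos[cand], -np.abs(t[cand]), p[cand]))
    return int(cand[order[0]])


def scan_cis(
    expr: ExpressionMatrix,
    gm: GenotypeMatrix,
    C: np.ndarray | pd.DataFrame | None = None,
    flank: int = CIS_FLANK_BP,
    keep_pairs: bool = False,
) -> CisScanResult:
    """Scan every exon's cis window; returns index-variant rows per exon.

    Exons without a testable (non-constant, in-window) variant are flagged
    with ``n_variants_tested = 0`` and NaN statistics; downstream FDR drops
    them.
    """
    n = len(expr.samples)
    if gm.n_samples != n or list(gm.samples) != list(expr.samples):
        raise ValueError("genotype and expression matrices disagree on samples")
    Q = covariate_basis(C, n)
    df = n - Q.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    rows = []
    pair_frames: list[pd.DataFrame] = []
    positions = gm.variants["pos"].to_numpy()
    vids = gm.variants["variant_id"].to_numpy()
    for i in range(expr.n_exons):
        ex = expr.exons.iloc[i]
        lo, hi = define_cis_window(int(ex["tss"]), flank)
        idx = _window_variant_indices(gm, ex["chrom"], lo, hi)
        base = {
            "exon_id": ex["exon_id"],
            "gene_id": ex["gene_id"],
            "chrom": str(ex["chrom"]),
            "tss": int(ex["tss"]),
        }
        if idx.size:
            G = gm.dosages[:, idx]
            nonconst = np.ptp(G, axis=0) > 0
            idx = idx[nonconst]
        if idx.size == 0:
            rows.append(
                base
                | {
                    "index_variant": None,
                    "index_pos": np.nan,
                    "beta": np.nan,
                    "se": np.nan,
                    "t_stat": np.nan,
                    "min_p": np.nan,
                    "tss_distance": np.nan,
                    "n_variants_tested": 0,
                }
            )
            continue
        G = gm.dosages[:, idx]
        y = expr.values[i]
        yr = y - Q @ (Q.T @ y)
        Gr = G - Q @ (Q.T @ G)
        beta, se, t, p = _partial_stats(yr, Gr, df)
        j = _pick_index(p, t, positions[idx])
        rows.append(
            base
            | {
                "index_variant": vids[idx[j]],
                "index_pos": int(positions[idx[j]]),
                "beta": beta[j],
                "se": se[j],
                "t_stat": t[j],
                "min_p": p[j],
                "tss_distance": int(positions[idx[j]]) - int(ex["tss"]),
                "n_variants_tested": int(idx.size),
            }
        )
        if keep_pairs:
            pair_frames.append(
                pd.DataFrame(
                    {
                        "exon_id": ex["exon_id"],
                        "gene_id": ex["gene_id"],
                        "variant_id": vids[idx],
                        "pos": positions[idx],
                        "beta": beta,
                        "se": se,
                        "t_stat": t,
                        "p": p,
                    }
                )
            )
    table = pd.DataFrame(rows)
    pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames else None
    return CisScanResult(table=table, pairs=pairs)


def tss_distance_summary(table: pd.DataFrame, within_bp: int = 250_000) -> float:
    """Fraction of index variants within ``within_bp`` of the TSS."""
    d = table["tss_distance"].to_numpy(dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no index variants to summarize")
    return float((np.abs(d) <= within_bp).mean())
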