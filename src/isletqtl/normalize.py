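"""Expression normalization: exon filtering, depth scaling, rank-normal
transform, hidden-factor covariates, and RPKM summaries.

The phenotype fed to the eQTL scan is built as
``filter_exons -> scale_to_median_depth -> log2(x+1) -> inverse normal`` per
exon, after which each exon row carries the exact multiset of normal scores
``PHI^-1((r - 0.5)/n)`` (average ranks on ties).  Hidden technical/biological
structure is captured by the top-k left singular vectors of the centered
sample x exon matrix — a deterministic factor-analysis stand-in for Bayesian
factor methods — and a sex indicator is always appended as a covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExonCountMatrix, ExpressionMatrix

RPKM_EXPRESSED_MIN = 0.1


def filter_exons(
    counts: ExonCountMatrix,
    max_zero_samples: int = 10,
    mode: str = "count",
    min_nonzero_fraction: float = 0.10,
) -> ExonCountMatrix:
    """Drop weakly expressed exons.

    ``mode="count"``: remove exons with zero counts in ``max_zero_samples``
    or more samples. ``mode="fraction"``: keep exons with non-zero counts in
    at least ``min_nonzero_fraction`` of samples.
    """
    zeros = (counts.counts == 0).sum(axis=1)
    if mode == "count":
        keep = zeros < max_zero_samples
    elif mode == "fraction":
        nonzero = counts.n_samples - zeros
        keep = nonzero >= min_nonzero_fraction * counts.n_samples
    else:
        raise ValueError(f"unknown exon filter mode {mode!r}")
    if not keep.any():
        raise ValueError("exon filter removed every exon")
    return counts.subset_exons(keep)


def scale_to_median_depth(counts: np.ndarray) -> np.ndarray:
    """Scale each sample (column) to the median per-sample total."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"samples with zero exon-mapped reads at columns {bad}")
    return counts * (np.median(totals) / totals)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """log2(x+1) followed by rank-based normal scores.

    Ranks receive PHI^-1((r - 0.5)/n) with average ranks on ties; the result
    is invariant to any strictly increasing transform of the input.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("constant vector has no rank-normal transform")
    x = np.log2(v + 1.0)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)


def normalize_counts(
    counts: ExonCountMatrix,
    max_zero_samples: int = 10,
    exon_filter_mode: str = "count",
    min_nonzero_fraction: float = 0.10,
) -> ExpressionMatrix:
    """Full normalization chain from raw exon counts to the scan phenotype."""
    filtered = filter_exons(
        counts,
        max_zero_samples=max_zero_samples,
        mode=exon_filter_mode,
        min_nonzero_fraction=min_nonzero_fraction,
    )
    scaled = scale_to_median_depth(filtered.counts)
    values = np.empty_like(scaled)
    for i in range(scaled.shape[0]):
        values[i] = inverse_normal_transform(scaled[i])
    return ExpressionMatrix(
        exons=filtered.exons.copy(), samples=list(filtered.samples), values=values
    )


def infer_hidden_factors(
    expr: ExpressionMatrix, k: int = 15, sex: np.ndarray | None = None
) -> pd.DataFrame:
    """Top-k left singular vectors of the sample x exon matrix as covariates.

    The expression matrix is centered per exon first; the returned factors
    are orthonormal across samples. A sex indicator, when provided, is always
    appended as an extra covariate column.
    """
    n = len(expr.samples)
    if k >= n:
        raise ValueError(f"k={k} factors require fewer than n={n} samples")
    cols: dict[str, np.ndarray] = {}
    if k > 0:
        x = expr.values - expr.values.mean(axis=1, keepdims=True)
        u, s, _ = np.linalg.svd(x.T, full_matrices=False)  # samples x exons
        for j in range(k):
            cols[f"factor_{j + 1}"] = u[:, j]
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
        if sex.size != n:
            raise ValueError("sex indicator length does not match samples")
        cols["sex"] = sex
    return pd.DataFrame(cols, index=list(expr.samples))


def factor_sex_screen(factors: pd.DataFrame, sex: np.ndarray) -> pd.DataFrame:
    """Diagnostic: correlation of each inferred factor with the sex indicator.

    Reported only; the pipeline appends sex as a covariate regardless.
    """
    from .permutation import storey_qvalues

    sex = np.asarray(sex, dtype=float)
    names = [c for c in factors.columns if c.startswith("factor_")]
    rows = []
    for c in names:
        r, p = stats.pearsonr(factors[c].to_numpy(), sex)
        rows.append({"factor": c, "pearson_r": r, "p": p})
    out = pd.DataFrame(rows)
    if len(out) > 0:
        q, _ = storey_qvalues(out["p"].to_numpy(), small_m_ok=True)
        out["q"] = q
    return out


def compute_rpkm(
    counts: np.ndarray, exon_lengths: np.ndarray, sample_totals: np.ndarray
) -> np.ndarray:
    """Reads per kilobase of exon per million mapped reads."""
    lengths = np.asarray(exon_lengths, dtype=float)
    totals = np.asarray(sample_totals, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("non-positive exon length")
    if (totals <= 0).any():
        raise ValueError("non-positive sample read total")
    c = np.asarray(counts, dtype=float)
    return c / (lengths[..., None] / 1e3) / (totals / 1e6)


def is_expressed(rpkm: np.ndarray | float) -> np.ndarray | bool:
    """RPKM at or above 0.1 counts as expressed (below is background)."""
    return np.asarray(rpkm) >= RPKM_EXPRESSED_MIN
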