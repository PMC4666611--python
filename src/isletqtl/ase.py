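"""Allele-specific expression testing across heterozygous carriers.

Per sample the statistic is the deviation of the alt-allele read fraction
from 0.5; samples below the depth floor and exact-0.5 fractions (zero
differences, classical Wilcoxon convention) are dropped and the remaining
deviations enter a two-sided Wilcoxon signed-rank test.  The exact null
distribution (uniform random signs conditional on the observed |d| ranks,
average ranks on ties) is used for n <= 25 via dynamic programming over
doubled ranks; larger n uses the normal approximation with continuity and
tie corrections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AseSiteCounts

EXACT_MAX_N = 25


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the rank vector."""
    ranks = stats.rankdata(np.abs(d), method="average")
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p under uniform sign assignment.

    Average ranks are half-integers at worst, so doubling makes them
    integers; the distribution of 2*W+ is built by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2.0 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with continuity correction and tie correction."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(d: np.ndarray) -> float:
    """Two-sided signed-rank p for a vector of differences (zeros dropped)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    w_plus, ranks = _signed_rank_statistic(d)
    if d.size <= EXACT_MAX_N:
        return _exact_signed_rank_p(w_plus, ranks)
    return _approx_signed_rank_p(w_plus, ranks)


def wilcoxon_ase_test(site: AseSiteCounts, min_depth: int = 10) -> float:
    """Allelic-imbalance p-value for one site across heterozygous samples."""
    depth = site.ref_counts + site.alt_counts
    keep = depth >= min_depth
    if not keep.any():
        raise ValueError(
            f"no sample at {site.variant_id} reaches depth >= {min_depth}"
        )
    frac = site.alt_counts[keep] / depth[keep]
    return wilcoxon_signed_rank(frac - 0.5)


def ase_report(sites: list[AseSiteCounts], min_depth: int = 10) -> pd.DataFrame:
    """Per-site summary: carriers used, median alt fraction, signed-rank p."""
    rows = []
    for site in sites:
        depth = site.ref_counts + site.alt_counts
        keep = depth >= min_depth
        frac = site.alt_counts[keep] / depth[keep]
        rows.append(
            {
                "variant_id": site.variant_id,
                "n_het": int(keep.sum()),
                "median_alt_fraction": float(np.median(frac)) if keep.any() else np.nan,
                "p": wilcoxon_ase_test(site, min_depth) if keep.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
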