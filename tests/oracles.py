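"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: integer combinatorics and exhaustive
enumeration, sharing no code path with the package.
"""

from itertools import product
from math import comb

import numpy as np
from scipy import stats


def hwe_enumeration_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by full enumeration with integer combinatorics.

    Conditional on n and the minor-allele count, P(het = h) =
    n! / (n_AA! h! n_aa!) * 2^h / C(2n, n_minor) (all integers); the p-value
    sums configurations no more probable than the observed one.
    """
    n = n_aa + n_ab + n_bb
    n_b = 2 * n_bb + n_ab
    n_minor = min(n_b, 2 * n - n_b)

    def weight(h: int) -> int:
        rare_hom = (n_minor - h) // 2
        common_hom = n - h - rare_hom
        # n! / (rare_hom! h! common_hom!) * 2^h as exact integer
        w = 1
        remaining = n
        for block in (rare_hom, h, common_hom):
            w *= comb(remaining, block)
            remaining -= block
        return w * 2**h

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


def fisher_enumeration_p(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> float:
    """Two-sided Fisher exact p for [[k_fg, n_fg-k_fg],[k_bg, n_bg-k_bg]]
    by hypergeometric enumeration with exact integer weights."""
    k_tot = k_fg + k_bg
    n_tot = n_fg + n_bg
    lo = max(0, k_tot - n_bg)
    hi = min(k_tot, n_fg)
    weights = {k: comb(n_fg, k) * comb(n_bg, k_tot - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    obs = weights[k_fg]
    return sum(w for w in weights.values() if w <= obs) / total


def signed_rank_enumeration_p(d: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p by exhausting all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d), method="average")
    w_obs = ranks[d > 0].sum()
    total = 2**n
    lower = upper = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs + 1e-9:
            lower += 1
        if w >= w_obs - 1e-9:
            upper += 1
    return min(1.0, 2.0 * min(lower, upper) / total)


def ols_normal_equations(y: np.ndarray, X: np.ndarray):
    """Brute-force OLS via explicit normal equations; returns coef, se, p."""
    n, k = X.shape
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    df = n - k
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return coef, se, p
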