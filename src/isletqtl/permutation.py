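"""Adaptive permutation empirical p-values and Storey q-value FDR.

Each permutation shuffles the genotype rows only, keeping expression and
covariates paired, and rescans the exon's full cis window for the permuted
minimum p.  Permutations run in batches; after each batch the scheme stops
once at least ``min_perm`` permutations have been done and at least
``stop_exceedances`` permuted minima beat the observed one, with a hard stop
at ``max_perm``.  The empirical p-value uses the (r+1)/(n+1) pseudo-count
convention, so it is always in (0, 1].

Because the permuted fits share the observed fit's residual degrees of
freedom, "permuted min p <= observed min p" is equivalent to "permuted max
partial r^2 >= observed max partial r^2", which is what the inner loop
compares — no per-permutation p-value evaluation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis import CIS_FLANK_BP, _window_variant_indices, covariate_basis, define_cis_window
from .core import ExpressionMatrix, GenotypeMatrix

# component tag for exon-indexed permutation seed streams
_PERM_STREAM = 0x5EED


@dataclass
class PermutationResult:
    exon_id: str
    n_permutations: int
    n_exceedances: int
    empirical_p: float
    seed: int


def _exceedances_batch(
    rng: np.random.Generator,
    n_perm: int,
    y_resid: np.ndarray,
    G: np.ndarray,
    Q: np.ndarray,
    raw_ss: np.ndarray,
    yss: float,
    r2_obs: float,
) -> int:
    """Count permutations whose max partial r^2 reaches the observed one.

    Permuting the genotype rows by pi is the same fit as permuting the
    (residual phenotype, covariate basis) rows by pi^-1, so the whole batch
    reduces to one batched matrix product of permuted [y_resid, Q] against
    the fixed dosage block.
    """
    n = y_resid.size
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    M = np.column_stack([y_resid, Q])  # n x (q+1)
    S = np.matmul(M[perms].transpose(0, 2, 1), G)  # n_perm x (q+1) x V
    num = S[:, 0, :]
    gss = raw_ss[None, :] - (S[:, 1:, :] ** 2).sum(axis=1)
    ok = gss > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ok, num**2 / np.where(ok, gss, 1.0) / yss, -np.inf)
    return int((r2.max(axis=1) >= r2_obs).sum())


def _adaptive_loop(
    count_exceedances,
    min_perm: int,
    max_perm: int,
    stop_exceedances: int,
    batch: int,
) -> tuple[int, int]:
    """Batched stop rule: stop once >= min_perm permutations are done and
    >= stop_exceedances permuted minima beat the observed one; hard stop at
    max_perm.  Checked at batch boundaries only."""
    done = 0
    exceed = 0
    while done < max_perm:
        m = min(batch, max_perm - done)
        exceed += count_exceedances(m)
        done += m
        if done >= min_perm and exceed >= stop_exceedances:
            break
    return done, exceed


def adaptive_permutation(
    y: np.ndarray,
    G: np.ndarray,
    Q: np.ndarray,
    seed: int,
    min_perm: int = 1000,
    max_perm: int = 10000,
    stop_exceedances: int = 15,
    batch: int = 1000,
    exon_id: str = "",
) -> PermutationResult:
    """Empirical p for one exon's observed minimum cis p-value.

    ``G`` holds the exon's in-window (non-constant) dosage columns, ``Q`` an
    orthonormal basis of [1, covariates] as built by
    :func:`isletqtl.cis.covariate_basis`.
    """
    y = np.asarray(y, dtype=float)
    yr = y - Q @ (Q.T @ y)
    yss = float(yr @ yr)
    raw_ss = np.einsum("ij,ij->j", G, G)
    qg = Q.T @ G
    gss = raw_ss - np.einsum("ij,ij->j", qg, qg)
    ok = gss > 1e-12
    if not ok.any():
        raise ValueError("no testable variant in window")
    num = yr @ G
    r2_obs = float(((num[ok] ** 2) / (gss[ok] * yss)).max())

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    done, exceed = _adaptive_loop(
        lambda m: _exceedances_batch(rng, m, yr, G, Q, raw_ss, yss, r2_obs),
        min_perm,
        max_perm,
        stop_exceedances,
        batch,
    )
    return PermutationResult(
        exon_id=exon_id,
        n_permutations=done,
        n_exceedances=exceed,
        empirical_p=(exceed + 1) / (done + 1),
        seed=seed,
    )


def exon_seed(master_seed: int, exon_index: int) -> int:
    """Exon-indexed child seed so every exon's stream is reproducible."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_PERM_STREAM, exon_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def permute_scan(
    expr: ExpressionMatrix,
    gm: GenotypeMatrix,
    scan_table: pd.DataFrame,
    C: np.ndarray | pd.DataFrame | None,
    master_seed: int,
    flank: int = CIS_FLANK_BP,
    min_perm: int = 1000,
    max_perm: int = 10000,
    stop_exceedances: int = 15,
    batch: int = 1000,
) -> pd.DataFrame:
    """Adaptive permutation for every scanned exon with >= 1 tested variant."""
    n = len(expr.samples)
    Q = covariate_basis(C, n)
    exon_pos = {str(e): i for i, e in enumerate(expr.exons["exon_id"])}
    out = scan_table.copy()
    out["n_permutations"] = 0
    out["n_exceedances"] = 0
    out["empirical_p"] = np.nan
    for row in scan_table.itertuples():
        if row.n_variants_tested == 0:
            continue
        i = exon_pos[str(row.exon_id)]
        ex = expr.exons.iloc[i]
        lo, hi = define_cis_window(int(ex["tss"]), flank)
        idx = _window_variant_indices(gm, ex["chrom"], lo, hi)
        G = gm.dosages[:, idx]
        G = G[:, np.ptp(G, axis=0) > 0]
        res = adaptive_permutation(
            expr.values[i],
            G,
            Q,
            seed=exon_seed(master_seed, i),
            min_perm=min_perm,
            max_perm=max_perm,
            stop_exceedances=stop_exceedances,
            batch=batch,
            exon_id=str(row.exon_id),
        )
        out.loc[row.Index, ["n_permutations", "n_exceedances", "empirical_p"]] = (
            res.n_permutations,
            res.n_exceedances,
            res.empirical_p,
        )
    return out


def storey_pi0(
    pvals: np.ndarray,
    lambdas: np.ndarray | None = None,
    small_m_ok: bool = False,
) -> float:
    """Storey-Tibshirani null-fraction estimate.

    Fits a cubic smoother to pi0(lambda) over the grid {0.05, ..., 0.95} and
    evaluates it at lambda = 0.95, clamped to (0, 1].  With fewer than 100
    p-values the grid is unstable, so a fixed lambda = 0.5 is used instead
    (with a warning unless ``small_m_ok``).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 100:
        if not small_m_ok:
            warnings.warn(
                f"only {m} p-values; using fixed lambda=0.5 for pi0", stacklevel=2
            )
        pi0 = float((p > 0.5).mean() / 0.5)
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.951, 0.05)
        counts = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, counts, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(
    pvals: np.ndarray, small_m_ok: bool = False, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """q-values via the step-up rule q(p_(i)) = min_{j>=i} pi0 * m * p_(j) / j.

    ``pi0`` overrides the estimated null fraction (e.g. 1.0 for plain
    Benjamini-Hochberg behaviour).
    """
    p = np.asarray(pvals, dtype=float)
    if pi0 is None:
        pi0 = storey_pi0(p, small_m_ok=small_m_ok)
    elif not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 override must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def fdr_table(
    perm_table: pd.DataFrame,
    q_threshold: float = 0.05,
    nominal_threshold: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Attach q-values and significance tiers to the permutation table."""
    out = perm_table.copy()
    tested = out["empirical_p"].notna()
    q = np.full(len(out), np.nan)
    q_sub, pi0 = storey_qvalues(
        out.loc[tested, "empirical_p"].to_numpy(), small_m_ok=True
    )
    q[tested.to_numpy()] = q_sub
    out["q"] = q
    out["significant"] = out["q"] < q_threshold
    out["nominal"] = out["empirical_p"] < nominal_threshold
    out["tier"] = np.where(
        out["significant"], "study_wide", np.where(out["nominal"], "nominal", "ns")
    )
    out.loc[~tested, "tier"] = "untested"
    return out, pi0


def estimate_pi1(replication_pvals: np.ndarray) -> float:
    """pi1 = 1 - pi0 of a replication p-value vector (the replication rate)."""
    p = np.asarray(replication_pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty replication p-value vector")
    if p.size < 100:
        warnings.warn(
            f"pi1 from only {p.size} p-values is unstable", stacklevel=2
        )
    return 1.0 - storey_pi0(p, small_m_ok=True)
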