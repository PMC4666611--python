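"""Overlap of variants with labeled chromatin states and enrichment testing.

Variants are 1-based points, intervals 0-based half-open; a variant at
position p overlaps [s, e) iff s < p <= e.  Overlap is taken as the union
over all requested states in all datasets ("active in at least one map"),
with per-dataset flags available.  Enrichment of a foreground variant set
against a background pool is tested both with Fisher's exact test on the
2x2 overlap table and with random resampling of foreground-sized draws from
the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ChromatinAnnotation

ACTIVE_STATES = frozenset({"enhancer", "promoter"})


def _merged_intervals(
    annotation: ChromatinAnnotation,
    states: frozenset[str] | set[str] | None,
    dataset: str | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays for the requested states."""
    df = annotation.intervals
    if states is not None:
        df = df[df["state"].isin(states)]
    if dataset is not None:
        df = df[df["dataset"] == dataset]
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        ivals = sub[["start", "end"]].to_numpy(int)
        ivals = ivals[np.argsort(ivals[:, 0], kind="stable")]
        starts, ends = [], []
        for s, e in ivals:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[str(chrom)] = (np.asarray(starts), np.asarray(ends))
    return merged


def overlap_variants(
    chroms: np.ndarray,
    positions: np.ndarray,
    annotation: ChromatinAnnotation,
    states: frozenset[str] | set[str] | None = ACTIVE_STATES,
    dataset: str | None = None,
) -> np.ndarray:
    """Boolean flag per variant: covered by any requested-state interval.

    ``states=None`` means any state (used for the "has any annotation"
    indicator). Variants on chromosomes absent from the annotation get a
    False flag with a warning.
    """
    chroms = np.asarray(chroms).astype(str)
    positions = np.asarray(positions, dtype=int)
    merged = _merged_intervals(annotation, states, dataset)
    flags = np.zeros(positions.size, dtype=bool)
    unknown = set()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        if chrom not in merged:
            if chrom not in {str(c) for c in annotation.intervals["chrom"].unique()}:
                unknown.add(chrom)
            continue
        starts, ends = merged[chrom]
        p0 = positions[mask] - 1  # 0-based point; covered iff start <= p0 < end
        k = np.searchsorted(starts, p0, side="right") - 1
        ok = k >= 0
        hit = np.zeros(p0.size, dtype=bool)
        hit[ok] = p0[ok] < ends[k[ok]]
        flags[mask] = hit
    if unknown:
        warnings.warn(
            f"variants on chromosomes with no annotation: {sorted(unknown)}",
            stacklevel=2,
        )
    return flags


@dataclass
class EnrichmentResult:
    n_fg: int
    n_fg_overlap: int
    n_bg: int
    n_bg_overlap: int
    fold: float
    fisher_p: float
    fisher_p_greater: float
    fisher_p_less: float
    resampling_p: float
    n_samplings: int
    fold_undefined: bool = False


def enrichment_test(
    fg_flags: np.ndarray,
    bg_flags: np.ndarray,
    n_samplings: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Fisher and resampling enrichment of foreground vs background overlap.

    ``fg_flags``/``bg_flags`` are boolean overlap indicators (from
    :func:`overlap_variants`).  Each resampling draws ``len(fg_flags)``
    variants from the background without replacement; the resampling p is
    (#{samplings with overlap count >= observed} + 1) / (n_samplings + 1).
    """
    fg = np.asarray(fg_flags, dtype=bool)
    bg = np.asarray(bg_flags, dtype=bool)
    n_fg, n_bg = fg.size, bg.size
    if n_bg < n_fg:
        raise ValueError("background pool smaller than foreground set")
    k_fg = int(fg.sum())
    k_bg = int(bg.sum())
    table = [[k_fg, n_fg - k_fg], [k_bg, n_bg - k_bg]]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    fisher_greater = float(stats.fisher_exact(table, alternative="greater")[1])
    fisher_less = float(stats.fisher_exact(table, alternative="less")[1])

    fold_undefined = k_bg == 0
    fold = np.inf if fold_undefined else (k_fg / n_fg) / (k_bg / n_bg)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = 0
    for _ in range(n_samplings):
        draw = rng.choice(n_bg, size=n_fg, replace=False)
        if int(bg[draw].sum()) >= k_fg:
            exceed += 1
    return EnrichmentResult(
        n_fg=n_fg,
        n_fg_overlap=k_fg,
        n_bg=n_bg,
        n_bg_overlap=k_bg,
        fold=float(fold),
        fisher_p=fisher_p,
        fisher_p_greater=fisher_greater,
        fisher_p_less=fisher_less,
        resampling_p=(exceed + 1) / (n_samplings + 1),
        n_samplings=n_samplings,
        fold_undefined=fold_undefined,
    )


def restricted_overlap_rate(
    overlap_flags: np.ndarray, annotated_flags: np.ndarray
) -> float:
    """Overlap rate after dropping variants absent from every annotation map."""
    overlap = np.asarray(overlap_flags, dtype=bool)
    annotated = np.asarray(annotated_flags, dtype=bool)
    n = int(annotated.sum())
    if n == 0:
        raise ValueError("no variant carries any chromatin annotation")
    return float(overlap[annotated].sum() / n)
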