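"""Core in-memory containers shared across the pipeline.

Coordinate conventions used throughout the package:

* variant and exon coordinates are 1-based, intervals inclusive on both ends;
* chromatin (BED) intervals are 0-based half-open and stay that way internally;
* a variant at 1-based position ``p`` overlaps a BED interval ``[s, e)``
  iff ``s < p <= e``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "genotyped", "info"]
EXON_COLUMNS = ["exon_id", "gene_id", "chrom", "start", "end", "strand", "tss"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages`` holds alt-allele dose in [0, 2]; ``NaN`` marks a missing call
    (allowed pre-QC only). ``variants`` is a DataFrame with the columns in
    :data:`VARIANT_COLUMNS`; ``info`` is the imputation quality (NaN means
    directly genotyped / no score, treated as 1.0 by QC).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n_s, n_v = self.dosages.shape
        if n_s != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but dosage matrix has {n_s} rows"
            )
        if n_v != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variant records but dosage matrix has {n_v} columns"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["variant_id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return int(hits[0])

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosages=self.dosages[:, keep].copy(),
        )

    def subset_samples(self, keep_samples: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        idx = [order[s] for s in keep_samples]
        return GenotypeMatrix(
            samples=list(keep_samples),
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :].copy(),
        )


@dataclass
class ExonCountMatrix:
    """Exons x samples integer read counts plus exon/gene annotation.

    ``exons`` has the columns in :data:`EXON_COLUMNS`; ``tss`` is the
    strand-aware transcription start site of the parent gene (annotated start
    for ``+`` genes, annotated end for ``-`` genes).
    """

    exons: pd.DataFrame
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (exons x samples)")
        n_e, n_s = self.counts.shape
        if n_e != len(self.exons):
            raise ValueError("exon annotation and count matrix disagree on exon count")
        if n_s != len(self.samples):
            raise ValueError("sample list and count matrix disagree on sample count")
        missing = [c for c in EXON_COLUMNS if c not in self.exons.columns]
        if missing:
            raise ValueError(f"exon table lacks columns: {missing}")
        if (self.exons["start"] > self.exons["end"]).any():
            raise ValueError("exon with start > end")
        self.exons = self.exons.reset_index(drop=True)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_exons(self, keep: np.ndarray) -> "ExonCountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExonCountMatrix(
            exons=self.exons.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
            counts=self.counts[keep, :].copy(),
        )

    def subset_samples(self, keep_samples: Sequence[str]) -> "ExonCountMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        idx = [order[s] for s in keep_samples]
        return ExonCountMatrix(
            exons=self.exons.copy(),
            samples=list(keep_samples),
            counts=self.counts[:, idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Exons x samples real-valued expression (normalized phenotype) matrix."""

    exons: pd.DataFrame
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.exons), len(self.samples)):
            raise ValueError("values shape does not match annotation/samples")
        self.exons = self.exons.reset_index(drop=True)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class ChromatinAnnotation:
    """Labeled genomic intervals (0-based half-open) from one or more datasets."""

    intervals: pd.DataFrame  # columns: chrom, start, end, state, dataset

    REQUIRED = ["chrom", "start", "end", "state", "dataset"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"interval table lacks columns: {missing}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("interval with start >= end")
        self.intervals = self.intervals.reset_index(drop=True)

    @property
    def states(self) -> set[str]:
        return set(self.intervals["state"].unique())

    @property
    def datasets(self) -> set[str]:
        return set(self.intervals["dataset"].unique())


@dataclass
class GwasLocus:
    """A reported GWAS lead variant with its trait annotation."""

    locus: str
    trait: str
    variant_id: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str


@dataclass
class AseSiteCounts:
    """Per-heterozygous-sample ref/alt read counts at one coding variant."""

    variant_id: str
    samples: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=int)
        self.alt_counts = np.asarray(self.alt_counts, dtype=int)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise ValueError("ref/alt count arrays differ in shape")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_het(self) -> int:
        return int(self.ref_counts.size)


@dataclass
class CisAssociation:
    """Single variant-exon additive-model regression result."""

    exon_id: str
    variant_id: str
    beta: float
    se: float
    t_stat: float
    p: float
    n: int
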