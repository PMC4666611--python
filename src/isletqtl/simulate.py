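"""Synthetic study generator: genotypes in LD blocks, exon counts with
planted cis effects and hidden confounders, GWAS loci sharing (or not) a
causal variant with a planted eQTL, chromatin states enriched around planted
variants, and ASE site counts.

LD within a block is generated from a latent founder haplotype pair that is
never emitted: each variant copies the founder allele per haplotype and
refreshes it with switch probability ``s`` from a fresh Bernoulli(maf) draw.
The correlation of any emitted variant with the founder is (1 - s), so every
*pairwise* emitted r^2 concentrates near (1 - s)^4; ``s`` is tuned so this
equals the block's target r^2.  Dosages are haplotype sums, hence
Hardy-Weinberg at the block MAF.

Expression: the latent per-exon signal is ``beta * dosage + loadings @
hidden_factors + noise``; counts are Poisson with log2-mean affine in the
latent signal plus the log library size, so the downstream normalization
chain (depth scaling, log2, rank-normal) approximately recovers the planted
beta on the inverse-normal scale.

All randomness flows from one master seed through named child streams
(genotypes / expression / GWAS / chromatin / ASE), so identical configs give
bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AseSiteCounts,
    ChromatinAnnotation,
    ExonCountMatrix,
    GenotypeMatrix,
    GwasLocus,
)

_STREAMS = {"genotypes": 1, "expression": 2, "gwas": 3, "chromatin": 4, "ase": 5}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Named child generator of the master seed (documented split scheme)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


@dataclass
class LdBlock:
    n_variants: int
    target_r2: float = 0.9
    maf: float = 0.3
    chrom: str = "1"
    start: int = 1_000_000
    spacing: int = 2_000


@dataclass
class GeneSpec:
    gene_id: str
    n_exons: int
    tss: int
    strand: str = "+"
    chrom: str = "1"
    exon_length: int = 200


@dataclass
class PlantedEqtl:
    gene_id: str
    variant_id: str
    beta: float
    flipped_exons: tuple[int, ...] = ()  # exon offsets with opposite effect sign


@dataclass
class SimConfig:
    """Study conditions for the synthetic islet cohort.

    Defaults mirror the real study design: 118 donors, 15 hidden covariates
    of technical/biological structure, library sizes spanning the reported
    29-165 million exon-mapped reads.
    """

    n_samples: int = 118
    ld_blocks: list[LdBlock] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    planted_eqtls: list[PlantedEqtl] = field(default_factory=list)
    n_hidden_factors: int = 15
    factor_sd: float = 0.5
    noise_sd: float = 1.0
    library_size_range: tuple[float, float] = (29e6, 165e6)
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for b in self.ld_blocks:
            if not (0.0 < b.maf <= 0.5):
                raise ValueError(f"block MAF {b.maf} outside (0, 0.5]")
            if not (0.0 <= b.target_r2 <= 1.0):
                raise ValueError(f"target r^2 {b.target_r2} outside [0, 1]")
            if b.n_variants < 1:
                raise ValueError("each block needs at least one variant")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library sizes must be positive with min <= max")
        for pq in self.planted_eqtls:
            if not np.isfinite(pq.beta):
                raise ValueError(f"non-finite beta for {pq.gene_id}")


@dataclass
class SimTruth:
    """Ground truth recorded alongside the emitted data."""

    planted: list[PlantedEqtl]
    factors: np.ndarray  # k x n_samples
    loadings: np.ndarray  # n_exons x k
    sex: np.ndarray  # n_samples, 1 = female
    sharing: dict[str, str | None] = field(default_factory=dict)  # locus -> eqtl variant


def variant_id_for(chrom: str, pos: int) -> str:
    return f"snp_{chrom}_{pos}"


def block_variant_ids(block: LdBlock) -> list[str]:
    return [
        variant_id_for(block.chrom, block.start + j * block.spacing)
        for j in range(block.n_variants)
    ]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Dosages in {0,1,2} under Hardy-Weinberg with block-level LD."""
    rng = child_rng(config.seed, "genotypes")
    n = config.n_samples
    records = []
    columns = []
    for block in config.ld_blocks:
        founder = rng.random((n, 2)) < block.maf
        s = 1.0 - block.target_r2**0.25
        for j in range(block.n_variants):
            pos = block.start + j * block.spacing
            if s == 0.0:
                hap = founder
            else:
                switch = rng.random((n, 2)) < s
                fresh = rng.random((n, 2)) < block.maf
                hap = np.where(switch, fresh, founder)
            columns.append(hap.sum(axis=1).astype(float))
            records.append(
                {
                    "variant_id": variant_id_for(block.chrom, pos),
                    "chrom": block.chrom,
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "genotyped": True,
                    "info": 1.0,
                }
            )
    samples = [f"sample_{i:03d}" for i in range(n)]
    return GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame(records),
        dosages=np.column_stack(columns) if columns else np.empty((n, 0)),
    )


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[ExonCountMatrix, SimTruth]:
    """Poisson exon counts whose latent log2 signal carries the planted betas."""
    rng = child_rng(config.seed, "expression")
    n = config.n_samples
    exon_rows = []
    gene_row_ranges: dict[str, tuple[int, int]] = {}
    row = 0
    for gene in config.genes:
        for e in range(gene.n_exons):
            offset = e * (gene.exon_length + 50)
            if gene.strand == "+":
                start = gene.tss + offset
            else:
                start = max(1, gene.tss - offset - gene.exon_length)
            exon_rows.append(
                {
                    "exon_id": f"{gene.gene_id}_exon{e + 1}",
                    "gene_id": gene.gene_id,
                    "chrom": gene.chrom,
                    "start": start,
                    "end": start + gene.exon_length - 1,
                    "strand": gene.strand,
                    "tss": gene.tss,
                }
            )
        gene_row_ranges[gene.gene_id] = (row, row + gene.n_exons)
        row += gene.n_exons
    n_exons = row
    exons = pd.DataFrame(exon_rows)

    latent = np.zeros((n_exons, n))
    for pq in config.planted_eqtls:
        if pq.gene_id not in gene_row_ranges:
            raise ValueError(f"planted eQTL names unknown gene {pq.gene_id!r}")
        try:
            dose = genotypes.dosage(pq.variant_id)
        except KeyError:
            raise ValueError(
                f"planted eQTL names unknown variant {pq.variant_id!r}"
            ) from None
        lo, hi = gene_row_ranges[pq.gene_id]
        for e, r in enumerate(range(lo, hi)):
            sign = -1.0 if e in pq.flipped_exons else 1.0
            latent[r] += sign * pq.beta * dose

    k = config.n_hidden_factors
    factors = rng.standard_normal((k, n)) * config.factor_sd
    loadings = rng.standard_normal((n_exons, k))
    if k > 0:
        latent += loadings @ factors
    latent += rng.standard_normal((n_exons, n)) * config.noise_sd

    sex = (rng.random(n) < config.female_fraction).astype(float)
    lo_lib, hi_lib = config.library_size_range
    lib = rng.uniform(lo_lib, hi_lib, size=n)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_exons)

    # fixed (sample-independent) denominator: per-sample totals then track the
    # library size up to Poisson/latent wobble without cancelling any shared
    # per-sample signal such as a planted effect common to a gene's exons
    weights = base[:, None] * np.exp2(np.clip(latent, -20.0, 20.0))
    mu = weights * (lib / base.sum())[None, :]
    counts = rng.poisson(mu).astype(np.int64)

    truth = SimTruth(
        planted=list(config.planted_eqtls),
        factors=factors,
        loadings=loadings,
        sex=sex,
    )
    return (
        ExonCountMatrix(exons=exons, samples=list(genotypes.samples), counts=counts),
        truth,
    )


def _ld_r2_matrix(dosages: np.ndarray, target: np.ndarray) -> np.ndarray:
    """r^2 of every dosage column with one target vector (NaN if constant)."""
    d = dosages - dosages.mean(axis=0)
    t = target - target.mean()
    denom = np.sqrt((d**2).sum(axis=0) * (t**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (t @ d) / denom
    return r**2


def simulate_gwas_loci(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    shared: list[bool],
    seed: int = 0,
    min_r2: float = 0.8,
    max_independent_r2: float = 0.05,
    lead_choice: str = "causal",
    trait: str = "T2D",
) -> list[GwasLocus]:
    """GWAS leads either sharing a planted causal variant or independent.

    A shared locus takes a planted eQTL variant and reports as lead either
    the causal variant itself (``lead_choice="causal"``, the package's
    definition of exact causal sharing) or its best non-identical proxy with
    r^2 > ``min_r2`` (``lead_choice="proxy"``).  An independent locus picks a
    variant with r^2 below ``max_independent_r2`` to every planted variant.
    """
    rng = child_rng(seed, "gwas")
    if lead_choice not in {"causal", "proxy"}:
        raise ValueError(f"unknown lead_choice {lead_choice!r}")
    planted_vids = [pq.variant_id for pq in truth.planted]
    planted_idx = [genotypes.index_of(v) for v in planted_vids]
    loci: list[GwasLocus] = []
    n_shared = 0
    for i, is_shared in enumerate(shared):
        name = f"locus_{i + 1}"
        if is_shared:
            if not planted_vids:
                raise ValueError("shared locus requested but no planted eQTLs")
            causal = planted_vids[n_shared % len(planted_vids)]
            n_shared += 1
            j_causal = genotypes.index_of(causal)
            if lead_choice == "causal":
                j_lead = j_causal
            else:
                r2 = _ld_r2_matrix(genotypes.dosages, genotypes.dosages[:, j_causal])
                r2[j_causal] = -1.0
                j_lead = int(np.nanargmax(r2))
                if not r2[j_lead] > min_r2:
                    raise ValueError(
                        f"no proxy with r^2 > {min_r2} for causal variant {causal}"
                    )
            truth.sharing[name] = causal
        else:
            ok = np.ones(genotypes.n_variants, dtype=bool)
            for j in planted_idx:
                r2 = _ld_r2_matrix(genotypes.dosages, genotypes.dosages[:, j])
                ok &= np.nan_to_num(r2, nan=1.0) < max_independent_r2
            candidates = np.flatnonzero(ok)
            if candidates.size == 0:
                raise ValueError(
                    "no variant independent of every planted eQTL "
                    f"(r^2 < {max_independent_r2})"
                )
            j_lead = int(rng.choice(candidates))
            truth.sharing[name] = None
        v = genotypes.variants.iloc[j_lead]
        loci.append(
            GwasLocus(
                locus=name,
                trait=trait,
                variant_id=str(v["variant_id"]),
                chrom=str(v["chrom"]),
                pos=int(v["pos"]),
                risk_allele=str(v["alt"]),
                other_allele=str(v["ref"]),
            )
        )
    return loci


def simulate_chromatin(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    enrichment_fold: float = 2.0,
    background_rate: float = 0.15,
    seed: int = 0,
    half_width: int = 100,
    other_state_rate: float = 0.2,
    datasets: tuple[str, ...] = ("islet_map1", "islet_map2"),
    guarantee_planted: bool = False,
) -> ChromatinAnnotation:
    """Enhancer/promoter intervals hitting planted variants at fold x background.

    Planted-eQTL variants receive an active-state interval with probability
    ``enrichment_fold * background_rate``; every other variant with
    probability ``background_rate``.  Independent "other"-state intervals are
    sprinkled at ``other_state_rate`` so that state filtering and the
    annotated-only denominator are exercised.

    ``guarantee_planted`` covers every planted variant with an active-state
    interval deterministically — used when a downstream test needs the
    chromatin gate to depend only on the nomination logic, not on the coin
    flips here (it makes the planted overlap rate 1, so enrichment folds are
    no longer calibrated).
    """
    if enrichment_fold < 1.0:
        raise ValueError("enrichment fold must be >= 1")
    fg_rate = enrichment_fold * background_rate
    if fg_rate > 1.0:
        raise ValueError(
            f"fold x background = {fg_rate:.3f} exceeds 1: not a probability"
        )
    rng = child_rng(seed, "chromatin")
    planted = {pq.variant_id for pq in truth.planted}
    rows = []
    for v in genotypes.variants.itertuples():
        is_planted = v.variant_id in planted
        rate = fg_rate if is_planted else background_rate
        pos0 = int(v.pos) - 1  # interval must satisfy start < pos <= end
        if (guarantee_planted and is_planted) or rng.random() < rate:
            state = "enhancer" if rng.random() < 0.7 else "promoter"
            rows.append(
                {
                    "chrom": str(v.chrom),
                    "start": max(0, pos0 - half_width),
                    "end": pos0 + half_width + 1,
                    "state": state,
                    "dataset": datasets[int(rng.integers(len(datasets)))],
                }
            )
        if rng.random() < other_state_rate:
            rows.append(
                {
                    "chrom": str(v.chrom),
                    "start": max(0, pos0 - half_width),
                    "end": pos0 + half_width + 1,
                    "state": "quiescent",
                    "dataset": datasets[int(rng.integers(len(datasets)))],
                }
            )
    if not rows:
        rows = []  # empty annotation is legal (background_rate = 0)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "dataset"])
    return ChromatinAnnotation(intervals=df)


def simulate_ase_counts(
    n_het: int,
    allelic_fraction: float,
    depth: int,
    seed: int = 0,
    variant_id: str = "ase_site",
) -> AseSiteCounts:
    """Binomial(depth, allelic_fraction) alt counts per heterozygous carrier."""
    if n_het <= 0:
        raise ValueError("need at least one heterozygous carrier")
    if not (0.0 < allelic_fraction < 1.0):
        raise ValueError("allelic fraction must be in (0, 1)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = child_rng(seed, "ase")
    alt = rng.binomial(depth, allelic_fraction, size=n_het)
    return AseSiteCounts(
        variant_id=variant_id,
        samples=[f"het_{i:03d}" for i in range(n_het)],
        ref_counts=depth - alt,
        alt_counts=alt,
    )


def paired_study_config(
    n_samples: int = 118,
    n_genes: int = 10,
    n_exons: int = 4,
    variants_per_block: int = 50,
    target_r2: float = 0.9,
    maf: float = 0.3,
    planted_beta: float = 1.0,
    planted_fraction: float = 0.3,
    n_hidden_factors: int = 15,
    factor_sd: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SimConfig:
    """Convenience layout: one LD block per gene, centered on its TSS.

    The first ``round(planted_fraction * n_genes)`` genes carry a planted
    eQTL at the middle variant of their block.
    """
    blocks, genes, planted = [], [], []
    gene_spacing = 3_000_000  # keeps cis windows disjoint
    for g in range(n_genes):
        tss = 2_000_000 + g * gene_spacing
        block = LdBlock(
            n_variants=variants_per_block,
            target_r2=target_r2,
            maf=maf,
            chrom="1",
            start=tss - (variants_per_block // 2) * 2_000,
            spacing=2_000,
        )
        blocks.append(block)
        genes.append(GeneSpec(gene_id=f"gene_{g + 1:02d}", n_exons=n_exons, tss=tss))
    n_planted = int(round(planted_fraction * n_genes))
    for g in range(n_planted):
        mid = block_variant_ids(blocks[g])[variants_per_block // 2]
        planted.append(
            PlantedEqtl(gene_id=f"gene_{g + 1:02d}", variant_id=mid, beta=planted_beta)
        )
    return SimConfig(
        n_samples=n_samples,
        ld_blocks=blocks,
        genes=genes,
        planted_eqtls=planted,
        n_hidden_factors=n_hidden_factors,
        factor_sd=factor_sd,
        noise_sd=noise_sd,
        seed=seed,
    )
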