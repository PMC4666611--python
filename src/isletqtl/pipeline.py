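"""Pipeline driver: QC -> normalization -> cis scan -> permutation FDR ->
GWAS colocalization -> chromatin enrichment (-> ASE), with TSV reports.

`run_study` operates on in-memory objects (what the tests and the synthetic
workflow use); `run_pipeline` wraps it with file input/output driven by a
:class:`isletqtl.io.PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ase import ase_report
from .chromatin import ACTIVE_STATES, EnrichmentResult, enrichment_test, overlap_variants
from .cis import CisScanResult, scan_cis
from .coloc import nominate_effectors
from .core import (
    AseSiteCounts,
    ChromatinAnnotation,
    ExonCountMatrix,
    ExpressionMatrix,
    GenotypeMatrix,
    GwasLocus,
)
from .io import FLOAT_FORMAT, PipelineConfig
from .normalize import infer_hidden_factors, normalize_counts
from .permutation import fdr_table, permute_scan
from .qc import filter_samples, filter_variants


@dataclass
class StudyResult:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    covariates: pd.DataFrame
    qc_report: pd.DataFrame
    scan: CisScanResult
    fdr: pd.DataFrame
    pi0: float
    gene_index: pd.DataFrame
    effectors: pd.DataFrame | None
    enrichment: EnrichmentResult | None
    overlap_fraction: float | None
    restricted_overlap_fraction: float | None
    ase: pd.DataFrame | None
    attrition: dict


def best_exon_per_gene(fdr: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: its best exon by empirical p (ties: q, then TSS)."""
    tested = fdr[fdr["empirical_p"].notna()]
    rows = []
    for _, sub in tested.groupby("gene_id", sort=True):
        rows.append(sub.sort_values(["empirical_p", "q", "tss"], kind="stable").iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


def _variant_overlap_stats(
    gene_index: pd.DataFrame,
    gm: GenotypeMatrix,
    annotation: ChromatinAnnotation,
    n_samplings: int,
    seed: int,
) -> tuple[EnrichmentResult | None, float | None, float | None]:
    """Enrichment of significant genes' index variants vs non-significant."""
    sig = gene_index[gene_index["significant"]]
    bg = gene_index[~gene_index["significant"]]
    if len(sig) == 0 or len(bg) < len(sig):
        return None, None, None
    vmeta = gm.variants.set_index("variant_id")

    def flags(table: pd.DataFrame, states) -> np.ndarray:
        sub = vmeta.loc[table["index_variant"]]
        return overlap_variants(
            sub["chrom"].astype(str).to_numpy(),
            sub["pos"].to_numpy(int),
            annotation,
            states=states,
        )

    fg_active = flags(sig, ACTIVE_STATES)
    bg_active = flags(bg, ACTIVE_STATES)
    fg_any = flags(sig, None)
    enr = enrichment_test(fg_active, bg_active, n_samplings=n_samplings, seed=seed)
    overlap_fraction = float(fg_active.mean())
    restricted = float(fg_active[fg_any].mean()) if fg_any.any() else None
    return enr, overlap_fraction, restricted


def run_study(
    gm: GenotypeMatrix,
    counts: ExonCountMatrix,
    gwas_loci: list[GwasLocus] | None = None,
    chromatin: ChromatinAnnotation | None = None,
    ase_sites: list[AseSiteCounts] | None = None,
    sex: np.ndarray | None = None,
    params: PipelineConfig | None = None,
) -> StudyResult:
    """Run the full analysis on in-memory inputs."""
    p = params or PipelineConfig()
    p.validate()
    attrition: dict = {"input_samples": counts.n_samples, "input_variants": gm.n_variants}

    keep_samples = filter_samples(counts, p.min_mapped_reads)
    if not keep_samples:
        raise ValueError("no sample reaches the mapped-read floor")
    sample_pos = {s: i for i, s in enumerate(counts.samples)}
    if sex is not None:
        sex = np.asarray(sex, dtype=float)[[sample_pos[s] for s in keep_samples]]
    counts = counts.subset_samples(keep_samples)
    gm = gm.subset_samples(keep_samples)
    attrition["samples_after_depth_filter"] = counts.n_samples

    gm, qc_report = filter_variants(
        gm,
        min_call_rate=p.min_call_rate,
        pre_imputation_maf=p.pre_imputation_maf,
        hwe_alpha=p.hwe_alpha,
        min_info=p.min_info,
        analysis_maf=p.analysis_maf,
    )
    attrition["variants_after_qc"] = gm.n_variants

    expr = normalize_counts(
        counts,
        max_zero_samples=p.max_zero_samples,
        exon_filter_mode=p.exon_filter_mode,
        min_nonzero_fraction=p.min_nonzero_fraction,
    )
    attrition["exons_after_filter"] = expr.n_exons

    covariates = infer_hidden_factors(expr, k=p.n_hidden_factors, sex=sex)
    C = covariates.to_numpy() if len(covariates.columns) else None

    scan = scan_cis(expr, gm, C, flank=p.cis_flank, keep_pairs=False)
    perm = permute_scan(
        expr,
        gm,
        scan.table,
        C,
        master_seed=p.seed,
        flank=p.cis_flank,
        min_perm=p.min_perm,
        max_perm=p.max_perm,
        stop_exceedances=p.stop_exceedances,
        batch=p.perm_batch,
    )
    fdr, pi0 = fdr_table(perm, p.q_threshold, p.nominal_threshold)
    gene_index = best_exon_per_gene(fdr)
    attrition["genes_tested"] = len(gene_index)
    attrition["significant_genes"] = int(gene_index["significant"].sum())

    effectors = None
    if gwas_loci is not None and chromatin is not None:
        effectors = nominate_effectors(
            fdr,
            gwas_loci,
            gm,
            expr,
            C,
            chromatin,
            r2_min=p.r2_min,
            coloc_alpha=p.coloc_alpha,
            q_threshold=p.q_threshold,
            nominal_threshold=p.nominal_threshold,
            flank=p.cis_flank,
        )

    enrichment = overlap_fraction = restricted = None
    if chromatin is not None:
        enrichment, overlap_fraction, restricted = _variant_overlap_stats(
            gene_index, gm, chromatin, p.n_samplings, p.seed
        )

    ase = ase_report(ase_sites, p.ase_min_depth) if ase_sites else None

    return StudyResult(
        genotypes=gm,
        expression=expr,
        covariates=covariates,
        qc_report=qc_report,
        scan=scan,
        fdr=fdr,
        pi0=pi0,
        gene_index=gene_index,
        effectors=effectors,
        enrichment=enrichment,
        overlap_fraction=overlap_fraction,
        restricted_overlap_fraction=restricted,
        ase=ase,
        attrition=attrition,
    )


def write_study_outputs(result: StudyResult, out_dir: str | Path, params: PipelineConfig | None = None) -> None:
    """Write every report table as deterministic TSV plus a JSON run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format=FLOAT_FORMAT)

    tsv(result.qc_report, "qc_report.tsv")
    tsv(result.fdr, "fdr_table.tsv")
    tsv(result.gene_index, "gene_index.tsv")
    tsv(result.covariates.reset_index(names="sample"), "covariates.tsv")
    if result.effectors is not None:
        tsv(result.effectors, "effector_report.tsv")
    if result.ase is not None:
        tsv(result.ase, "ase_report.tsv")
    log = {
        "isletqtl_version": __version__,
        "python": platform.python_version(),
        "attrition": result.attrition,
        "pi0": result.pi0,
    }
    if params is not None:
        log["params"] = dataclasses.asdict(params)
    if result.enrichment is not None:
        log["enrichment"] = dataclasses.asdict(result.enrichment)
        log["overlap_fraction"] = result.overlap_fraction
        log["restricted_overlap_fraction"] = result.restricted_overlap_fraction
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """File-driven pipeline entry point."""
    from .io import (
        read_ase_counts,
        read_bed_states,
        read_exon_counts,
        read_gwas_leads,
        read_vcf_dosages,
    )

    config.validate()
    if config.vcf is None or config.exon_counts is None:
        raise ValueError("pipeline requires at least vcf and exon_counts inputs")
    gm = read_vcf_dosages(config.vcf)
    counts = read_exon_counts(config.exon_counts)
    gwas = read_gwas_leads(config.gwas_leads) if config.gwas_leads else None
    chromatin = read_bed_states(config.chromatin_bed) if config.chromatin_bed else None
    ase_sites = read_ase_counts(config.ase_counts) if config.ase_counts else None
    result = run_study(gm, counts, gwas, chromatin, ase_sites, params=config)
    write_study_outputs(result, config.out_dir, params=config)
    return result
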