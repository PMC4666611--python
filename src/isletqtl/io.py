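"""Readers and writers for the pipeline's file formats.

All inputs and outputs are plain text (gzip accepted transparently on
reading): VCF with GT and DS fields for genotypes, TSV for exon counts /
annotation / GWAS leads / ASE counts / reports, BED with a state label (4th
column) and optional dataset id (5th column) for chromatin, JSON for the
simulation truth, YAML for the pipeline configuration.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import yaml

from .core import (
    AseSiteCounts,
    ChromatinAnnotation,
    ExonCountMatrix,
    ExpressionMatrix,
    GenotypeMatrix,
    GwasLocus,
    EXON_COLUMNS,
)

FLOAT_FORMAT = "%.10g"


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF


def read_vcf_dosages(path: str | Path, info_key: str = "INFO") -> GenotypeMatrix:
    """Genotype dosages from a VCF; DS preferred over GT, missing -> NaN.

    Multi-allelic records are skipped with a warning.  The imputation
    quality is read from ``info_key`` in the INFO column when present (NaN
    otherwise); a record with ``TYPED`` in INFO is flagged as directly
    genotyped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    columns = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record at {rec.CHROM}:{rec.POS}",
                stacklevel=2,
            )
            continue
        ds = rec.format("DS")
        if ds is not None:
            # DS arrives as float32; round off the representation noise
            col = np.round(np.asarray(ds, dtype=float).reshape(-1), 6)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = np.asarray(rec.gt_types)
            col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        info_val = rec.INFO.get(info_key)
        records.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "genotyped": rec.INFO.get("TYPED") is not None,
                "info": float(info_val) if info_val is not None else np.nan,
            }
        )
        columns.append(col)
    n = len(samples)
    dosages = np.column_stack(columns) if columns else np.empty((n, 0))
    return GenotypeMatrix(samples=samples, variants=pd.DataFrame(records), dosages=dosages)


def write_vcf(gm: GenotypeMatrix, path: str | Path, info_key: str = "INFO") -> None:
    """Write a minimal VCF with GT + DS; integral dosages get hard GT calls."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={info_key},Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(gm.variants.itertuples()):
            info_parts = []
            if not np.isnan(v.info):
                info_parts.append(f"{info_key}={v.info:g}")
            if v.genotyped:
                info_parts.append("TYPED")
            info_str = ";".join(info_parts) if info_parts else "."
            fields = [
                str(v.chrom), str(v.pos), str(v.variant_id), str(v.ref),
                str(v.alt), ".", "PASS", info_str, "GT:DS",
            ]
            for d in gm.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                elif float(d).is_integer():
                    fields.append(f"{gts[int(d)]}:{d:g}")
                else:
                    fields.append(f"./.:{d:g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# exon counts and expression


def write_exon_counts(counts: ExonCountMatrix, path: str | Path) -> None:
    df = pd.concat(
        [
            counts.exons[EXON_COLUMNS].reset_index(drop=True),
            pd.DataFrame(counts.counts, columns=counts.samples),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)


def read_exon_counts(path: str | Path) -> ExonCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_exon_columns(df, path)
    sample_cols = [c for c in df.columns if c not in EXON_COLUMNS]
    return ExonCountMatrix(
        exons=df[EXON_COLUMNS].copy(),
        samples=sample_cols,
        counts=df[sample_cols].to_numpy(np.int64),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.concat(
        [
            expr.exons[EXON_COLUMNS].reset_index(drop=True),
            pd.DataFrame(expr.values, columns=expr.samples),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_exon_columns(df, path)
    sample_cols = [c for c in df.columns if c not in EXON_COLUMNS]
    return ExpressionMatrix(
        exons=df[EXON_COLUMNS].copy(),
        samples=sample_cols,
        values=df[sample_cols].to_numpy(float),
    )


def _check_exon_columns(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EXON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing exon annotation columns {missing}")
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"{path}: exon start > end at data line {bad[0] + 1}")


def read_exon_table(path: str | Path) -> pd.DataFrame:
    """Exon annotation only; fills TSS from start/end by strand if absent."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "tss" not in df.columns:
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    _check_exon_columns(df, path)
    return df[EXON_COLUMNS].copy()


# ---------------------------------------------------------------------------
# BED chromatin states


def read_bed_states(path: str | Path, default_dataset: str = "dataset1") -> ChromatinAnnotation:
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs >= 4 columns")
            chrom, start, end, state = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            dataset = parts[4] if len(parts) > 4 else default_dataset
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "state": state, "dataset": dataset}
            )
    return ChromatinAnnotation(
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "dataset"])
    )


def write_bed_states(annotation: ChromatinAnnotation, path: str | Path) -> None:
    annotation.intervals.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# GWAS leads


def read_gwas_leads(path: str | Path) -> list[GwasLocus]:
    df = pd.read_csv(path, sep="\t")
    required = ["locus", "trait", "variant_id", "chrom", "pos", "risk_allele", "other_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing GWAS lead columns {missing}")
    return [
        GwasLocus(
            locus=str(r.locus),
            trait=str(r.trait),
            variant_id=str(r.variant_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            risk_allele=str(r.risk_allele),
            other_allele=str(r.other_allele),
        )
        for r in df.itertuples()
    ]


def write_gwas_leads(loci: list[GwasLocus], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(l) for l in loci]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ASE counts


def read_ase_counts(path: str | Path) -> list[AseSiteCounts]:
    df = pd.read_csv(path, sep="\t")
    required = ["variant_id", "sample", "ref_count", "alt_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ASE columns {missing}")
    sites = []
    for vid, sub in df.groupby("variant_id", sort=True):
        sites.append(
            AseSiteCounts(
                variant_id=str(vid),
                samples=[str(s) for s in sub["sample"]],
                ref_counts=sub["ref_count"].to_numpy(int),
                alt_counts=sub["alt_count"].to_numpy(int),
            )
        )
    return sites


def write_ase_counts(sites: list[AseSiteCounts], path: str | Path) -> None:
    rows = []
    for site in sites:
        for s, r, a in zip(site.samples, site.ref_counts, site.alt_counts):
            rows.append(
                {"variant_id": site.variant_id, "sample": s, "ref_count": int(r), "alt_count": int(a)}
            )
    pd.DataFrame(rows, columns=["variant_id", "sample", "ref_count", "alt_count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# simulation truth


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "planted": [dataclasses.asdict(p) for p in truth.planted],
        "factors": np.asarray(truth.factors).tolist(),
        "loadings": np.asarray(truth.loadings).tolist(),
        "sex": np.asarray(truth.sex).tolist(),
        "sharing": truth.sharing,
    }
    with _open_text(path, "wt") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path: str | Path):
    from .simulate import PlantedEqtl, SimTruth

    with _open_text(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        planted=[
            PlantedEqtl(
                gene_id=p["gene_id"],
                variant_id=p["variant_id"],
                beta=p["beta"],
                flipped_exons=tuple(p.get("flipped_exons", ())),
            )
            for p in payload["planted"]
        ],
        factors=np.asarray(payload["factors"]),
        loadings=np.asarray(payload["loadings"]),
        sex=np.asarray(payload["sex"]),
        sharing=payload.get("sharing", {}),
    )


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All file paths and thresholds of one pipeline run.

    Threshold defaults are the study's published analysis settings.
    """

    vcf: str | None = None
    exon_counts: str | None = None
    gwas_leads: str | None = None
    chromatin_bed: str | None = None
    ase_counts: str | None = None
    out_dir: str = "isletqtl_out"

    min_call_rate: float = 0.99
    pre_imputation_maf: float = 0.01
    hwe_alpha: float = 1e-4
    min_info: float = 0.4
    analysis_maf: float = 0.05
    min_mapped_reads: int = 10_000_000
    max_zero_samples: int = 10
    exon_filter_mode: str = "count"
    min_nonzero_fraction: float = 0.10
    n_hidden_factors: int = 15
    cis_flank: int = 1_000_000
    min_perm: int = 1000
    max_perm: int = 10000
    stop_exceedances: int = 15
    perm_batch: int = 1000
    q_threshold: float = 0.05
    nominal_threshold: float = 0.05
    r2_min: float = 0.8
    coloc_alpha: float = 0.05
    n_samplings: int = 10000
    rpkm_expressed_min: float = 0.1
    ase_min_depth: int = 10
    seed: int = 0

    def validate(self) -> None:
        in_unit = {
            "min_call_rate": self.min_call_rate,
            "pre_imputation_maf": self.pre_imputation_maf,
            "hwe_alpha": self.hwe_alpha,
            "min_info": self.min_info,
            "analysis_maf": self.analysis_maf,
            "q_threshold": self.q_threshold,
            "nominal_threshold": self.nominal_threshold,
            "r2_min": self.r2_min,
            "coloc_alpha": self.coloc_alpha,
            "min_nonzero_fraction": self.min_nonzero_fraction,
        }
        for name, v in in_unit.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_perm < 1 or self.max_perm < self.min_perm:
            raise ValueError("need 1 <= min_perm <= max_perm")
        if self.cis_flank < 0:
            raise ValueError("cis_flank must be non-negative")


def read_config(path: str | Path) -> PipelineConfig:
    with _open_text(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
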