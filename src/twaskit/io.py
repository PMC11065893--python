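"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF (GT + per-sample DS dosage + INFO/R2 imputation
quality); phenotypes, covariates, summary statistics, weight databases and
results as TSV; pipeline configuration as YAML.  Coordinates are 1-based
inclusive everywhere (the VCF convention); feature-anchor BED input is
converted from 0-based half-open on read.  All writers order rows stably
(layer, feature, chrom, pos) so identical inputs give identical files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import (
    DataError,
    GenotypeMatrix,
    GwasSummaryStats,
    MolecularPhenotypeMatrix,
    SUMSTAT_COLUMNS,
    WeightDB,
    WeightModel,
)

WEIGHTDB_COLUMNS = [
    "layer", "feature_id", "variant_id", "chrom", "pos",
    "effect_allele", "other_allele", "weight", "cv_r", "n_nonzero", "lambda",
]


# ---------------------------------------------------------------------------
# VCF

def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Dosage comes from FORMAT/DS when present, otherwise from the GT
    alternate-allele count; missing genotypes become NaN.  Multi-allelic
    records are kept but flagged for QC.  INFO/R2 is picked up as the
    imputation quality when present.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for i, rec in enumerate(vcf):
        if rec.ALT is None or len(rec.ALT) == 0:
            raise DataError(f"record {i + 1} ({rec.CHROM}:{rec.POS}): no ALT allele")
        multi = len(rec.ALT) > 1
        ds = None
        try:
            ds_arr = rec.format("DS")
            if ds_arr is not None:
                ds = np.asarray(ds_arr, dtype=float).reshape(len(samples), -1)[:, 0]
                ds = np.where((ds < -0.5) | (ds > 2.5), np.nan, ds)
        except KeyError:
            ds = None
        if ds is not None and np.isfinite(ds).any():
            dose = ds
            gt_missing = np.array([g[0] is None or g[0] < 0 for g in rec.genotypes])
            dose = np.where(np.isnan(dose) & ~gt_missing,
                            _gt_dosage(rec.genotypes), dose)
        else:
            if rec.genotypes is None:
                raise DataError(
                    f"record {i + 1} ({rec.CHROM}:{rec.POS}): neither GT nor DS present"
                )
            dose = _gt_dosage(rec.genotypes)
        r2 = rec.INFO.get("R2")
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        rows.append(
            {
                "variant_id": vid, "chrom": rec.CHROM, "pos": rec.POS,
                "ref": rec.REF, "alt": ",".join(rec.ALT) if multi else rec.ALT[0],
                "imputation_r2": float(r2) if r2 is not None else np.nan,
                "multiallelic": multi,
            }
        )
        dosage_cols.append(dose)
    if not rows:
        raise DataError(f"no variant records in {path}")
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(samples=samples, dosages=dosages, variants=pd.DataFrame(rows))


def _gt_dosage(genotypes: list) -> np.ndarray:
    out = np.empty(len(genotypes))
    for s, g in enumerate(genotypes):
        alleles = [a for a in g[:-1] if a is not None and a >= 0]
        out[s] = sum(1 for a in alleles if a > 0) if alleles else np.nan
    return out


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF (GT:DS, INFO/R2).

    DS always carries the exact dosage (6 decimals); GT is the rounded hard
    call when the dosage is within 0.1 of an integer, otherwise './.'.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        for chrom in dict.fromkeys(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        order = geno.variants.sort_values(["chrom", "pos"], kind="mergesort").index
        for j in order:
            v = geno.variants.loc[j]
            r2 = v["imputation_r2"]
            info = f"R2={r2:.6g}" if pd.notna(r2) else "."
            cells = []
            for d in geno.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                    continue
                hard = int(round(d))
                if abs(d - hard) <= 0.1:
                    gt = ["0/0", "0/1", "1/1"][hard]
                else:
                    gt = "./."
                cells.append(f"{gt}:{d:.6f}")
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# GWAS summary statistics

def read_gwas_sumstats(path: str | Path) -> tuple[GwasSummaryStats, int]:
    """Read a summary-statistics TSV; returns (stats, n_rejected_rows).

    Rows with se <= 0 or EAF outside (0, 1) are rejected and counted.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"summary statistics file missing column(s): {', '.join(missing)}")
    bad = (df["se"] <= 0) | (df["eaf"] <= 0) | (df["eaf"] >= 1) | df["se"].isna()
    rejected = int(bad.sum())
    return GwasSummaryStats(df[~bad].reset_index(drop=True)), rejected


def write_gwas_sumstats(stats: GwasSummaryStats, path: str | Path) -> None:
    out = stats.table.sort_values(["chrom", "pos"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes / covariates

def write_phenotypes_tsv(m: MolecularPhenotypeMatrix, path: str | Path) -> None:
    """Feature rows x sample columns, with anchor columns up front."""
    anchors = m.anchors[["chrom", "start", "end", "strand"]]
    out = pd.concat([anchors, m.values], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_phenotypes_tsv(path: str | Path, layer: str,
                        is_transformed: bool = False) -> MolecularPhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    anchor_cols = ["chrom", "start", "end", "strand"]
    missing = [c for c in anchor_cols if c not in df.columns]
    if missing:
        raise DataError(f"phenotype file missing anchor column(s): {', '.join(missing)}")
    anchors = df[anchor_cols].copy()
    anchors["chrom"] = anchors["chrom"].astype(str)
    values = df.drop(columns=anchor_cols)
    return MolecularPhenotypeMatrix(layer=layer, values=values, anchors=anchors,
                                    is_transformed=is_transformed)


def read_feature_bed(path: str | Path) -> pd.DataFrame:
    """Feature anchors from BED (0-based half-open) -> 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise DataError("feature BED needs at least chrom/start/end/name columns")
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0].astype(str).to_numpy(),
            "start": df.iloc[:, 1].astype(int).to_numpy() + 1,
            "end": df.iloc[:, 2].astype(int).to_numpy(),
            "strand": df.iloc[:, 5].to_numpy() if df.shape[1] > 5 else "+",
        },
        index=pd.Index(df.iloc[:, 3].to_numpy(), name="feature_id"),
    )
    return out


def write_covariates_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# Weight database

def write_weightdb_tsv(db: WeightDB, path: str | Path) -> None:
    rows = []
    for (layer, fid), model in sorted(db.models.items()):
        for _, w in model.weights.iterrows():
            rows.append(
                {
                    "layer": layer, "feature_id": fid,
                    "variant_id": w["variant_id"], "chrom": w["chrom"],
                    "pos": w["pos"], "effect_allele": w["effect_allele"],
                    "other_allele": w["other_allele"],
                    "weight": repr(float(w["weight"])),
                    "cv_r": repr(float(model.cv_r)),
                    "n_nonzero": model.n_nonzero, "lambda": repr(float(model.lambda_)),
                }
            )
    out = pd.DataFrame(rows, columns=WEIGHTDB_COLUMNS)
    if len(out):
        out = out.sort_values(["layer", "feature_id", "chrom", "pos"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_weightdb_tsv(path: str | Path, r_threshold: float = 0.1) -> WeightDB:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHTDB_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"weight DB file missing column(s): {', '.join(missing)}")
    db = WeightDB(r_threshold=r_threshold)
    if len(df) == 0:
        return db
    if df.duplicated(["layer", "feature_id", "variant_id"]).any():
        raise DataError("duplicate (feature, variant) rows in weight DB file")
    for (layer, fid), grp in df.groupby(["layer", "feature_id"], sort=True):
        weights = grp[["variant_id", "chrom", "pos", "effect_allele",
                       "other_allele", "weight"]].reset_index(drop=True)
        db.add(
            WeightModel(
                feature_id=str(fid), layer=str(layer), weights=weights,
                cv_r=float(grp["cv_r"].iloc[0]), lambda_=float(grp["lambda"].iloc[0]),
            )
        )
    return db


# ---------------------------------------------------------------------------
# Results / truth / config

def write_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (paths + thresholds + seed)."""

    panel_vcf: str = ""
    gwas_stats: str = ""
    phenotype_tsvs: dict = dataclasses.field(default_factory=dict)  # layer -> path
    covariates_tsv: str = ""
    out_dir: str = "twaskit_out"
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    missing_max: float = 0.05
    imputation_r2_min: float = 0.8
    cis_window: int = 500_000
    alpha: float = 0.5
    folds: int = 5
    r_threshold: float = 0.1
    max_perm: int = 1000
    perm_entry_threshold: float = 0.05
    n_factors: int | None = None
    seed: int = 0
    layers: tuple = ("expression",)

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise DataError("cis_window must be positive")
        for name in ("maf_min", "hwe_p_min", "missing_max", "perm_entry_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise DataError(f"{name} must lie in [0, 1]")
        if not (0 < self.alpha <= 1):
            raise DataError("alpha must lie in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["layers"] = list(self.layers)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "layers" in payload:
            payload["layers"] = tuple(payload["layers"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise DataError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**payload)
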