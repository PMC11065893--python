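"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of data around: a reference-panel genotype
matrix, molecular phenotype matrices for the three layers (gene expression
TPM, 3'UTR alternative-polyadenylation PDUI, exon-junction PSI), GWAS
summary statistics, and per-feature SNP weight models.  Each container is a
thin dataclass over numpy / pandas with schema validation, so every module
can rely on the same invariants (dosages in [0, 2], se > 0, EAF in (0, 1),
anchors with start <= end, ...).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LAYERS = ("expression", "apa", "junction")

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "imputation_r2", "multiallelic",
]

SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

WEIGHT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight",
]


class ConfigurationError(ValueError):
    """Raised for invalid configuration values."""


class DataError(ValueError):
    """Raised for malformed or internally inconsistent data."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{what} is missing required column(s): {', '.join(missing)}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages`` holds alternate-allele dosages in [0, 2]; NaN marks a missing
    genotype.  ``variants`` has one row per variant with columns
    ``variant_id, chrom, pos, ref, alt, imputation_r2, multiallelic``
    (``imputation_r2`` may be NaN for directly genotyped variants).
    """

    samples: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        _require_columns(self.variants, VARIANT_COLUMNS, "variant table")
        self.variants = self.variants.reset_index(drop=True)
        if (self.variants["pos"] < 1).any():
            raise DataError("variant positions must be 1-based (>= 1)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or \
               np.nanmax(self.dosages, initial=0.0) > 2.0 + 1e-9:
                raise DataError("dosages must lie in [0, 2]")
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants["variant_id"][self.variants["variant_id"].duplicated()]
            raise DataError(f"duplicate variant ids: {sorted(set(dup))[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, variant_ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Index(self.variants["variant_id"])
        idx = lookup.get_indexer(variant_ids)
        if (idx < 0).any():
            absent = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise DataError(f"variants absent from panel: {absent[:5]}")
        return idx

    def dosage_for(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Dosage columns for the given variants, in the given order."""
        return self.dosages[:, self.index_of(variant_ids)]

    def subset_variants(self, keep: np.ndarray | Sequence[str]) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.index_of(list(keep))
        return GenotypeMatrix(
            samples=list(self.samples),
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def alt_freqs(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries filled by the per-variant mean."""
        filled = self.dosages.copy()
        if np.isnan(filled).any():
            col_means = np.nanmean(filled, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(filled))
            filled[nan_r, nan_c] = col_means[nan_c]
        return filled


@dataclass
class MolecularPhenotypeMatrix:
    """Features x samples molecular phenotype matrix with genomic anchors.

    ``layer`` is one of ``expression`` (TPM >= 0, or log2-transformed after
    preparation), ``apa`` (PDUI in [0, 1]) or ``junction`` (PSI in [0, 1]).
    ``anchors`` is indexed by feature id with columns chrom/start/end/strand.
    NaN marks a missing quantification.
    """

    layer: str
    values: pd.DataFrame
    anchors: pd.DataFrame
    is_transformed: bool = False

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise DataError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        _require_columns(self.anchors, ["chrom", "start", "end", "strand"], "anchor table")
        if not self.values.index.equals(self.anchors.index):
            if set(self.values.index) != set(self.anchors.index):
                raise DataError("values and anchors must describe the same features")
            self.anchors = self.anchors.loc[self.values.index]
        if (self.anchors["start"] > self.anchors["end"]).any():
            raise DataError("anchor start must be <= end")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if self.is_transformed:
                pass  # normalized/residualized values are unbounded
            elif self.layer in ("apa", "junction"):
                if np.nanmin(vals, initial=0.0) < -1e-9 or np.nanmax(vals, initial=0.0) > 1 + 1e-9:
                    raise DataError(f"{self.layer} values must lie in [0, 1]")
            elif np.nanmin(vals, initial=0.0) < -1e-9:
                raise DataError("TPM values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, *, transformed: bool | None = None) -> "MolecularPhenotypeMatrix":
        return MolecularPhenotypeMatrix(
            layer=self.layer,
            values=values,
            anchors=self.anchors.loc[values.index],
            is_transformed=self.is_transformed if transformed is None else transformed,
        )


@dataclass
class CovariateMatrix:
    """Samples x covariates design block (age, genotype PCs, latent factors)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise DataError("covariates must not contain missing values")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    def to_numpy(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class GwasSummaryStats:
    """Per-variant marginal GWAS association statistics.

    Columns: ``variant_id, chrom, pos, effect_allele, other_allele, eaf,
    beta, se, p, n``.  ``beta`` is the per-allele effect on the log-odds
    (case-control) or linear scale; ``se`` its standard error.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.table, SUMSTAT_COLUMNS, "summary statistics")
        self.table = self.table.reset_index(drop=True)
        if self.table["variant_id"].duplicated().any():
            raise DataError("duplicate variant ids in summary statistics")
        if (self.table["se"] <= 0).any():
            raise DataError("summary statistics require se > 0")
        eaf = self.table["eaf"]
        if ((eaf <= 0) | (eaf >= 1)).any():
            raise DataError("summary statistics require eaf strictly in (0, 1)")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("variant_id", drop=False)


@dataclass
class WeightModel:
    """Trained cis prediction model for one molecular feature.

    ``weights`` has one row per cis variant (effect allele = allele whose
    dosage the weight multiplies); ``cv_r`` is the signed Pearson correlation
    between cross-validated predictions and the observed phenotype.
    """

    feature_id: str
    layer: str
    weights: pd.DataFrame
    cv_r: float
    lambda_: float = float("nan")
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        _require_columns(self.weights, WEIGHT_COLUMNS, "weight table")
        self.weights = self.weights.reset_index(drop=True)
        if self.weights["variant_id"].duplicated().any():
            raise DataError(f"duplicate variants in model for {self.feature_id}")
        if not (-1 - 1e-9 <= self.cv_r <= 1 + 1e-9):
            raise DataError("cv_r must lie in [-1, 1]")

    @property
    def n_nonzero(self) -> int:
        return int((self.weights["weight"] != 0).sum())

    def nonzero(self) -> "WeightModel":
        kept = self.weights[self.weights["weight"] != 0].reset_index(drop=True)
        return replace(self, weights=kept)

    @property
    def key(self) -> tuple[str, str]:
        return (self.layer, self.feature_id)


@dataclass
class WeightDB:
    """Collection of retained weight models plus model-building tallies.

    ``counts`` records, per layer, how many features model building was
    attempted for, how many yielded a predictable model (>= 1 non-zero
    weight), and how many were retained at the cv-R threshold.
    """

    models: dict[tuple[str, str], WeightModel] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    r_threshold: float = 0.1

    def add(self, model: WeightModel) -> None:
        if model.key in self.models:
            raise DataError(f"duplicate model key {model.key}")
        self.models[model.key] = model

    def per_layer(self, layer: str) -> list[WeightModel]:
        return [m for (lay, _), m in self.models.items() if lay == layer]

    @property
    def layers(self) -> list[str]:
        return sorted({lay for (lay, _) in self.models})

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class ReferenceCovariance:
    """Reference-panel covariance over a model's variants.

    ``matrix`` is the sample covariance (denominator n-1) of mean-centered
    dosages; ``sigma`` are the per-variant SDs and ``sigma_g(w)`` the SD of
    the weighted genotype score w'X.
    """

    variant_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.variant_ids)
        if self.matrix.shape != (k, k):
            raise DataError("covariance matrix shape does not match variant ids")
        if k and not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise DataError("covariance matrix must be symmetric")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.matrix), 0.0, None))

    def sigma_g(self, w: np.ndarray, ridge: float = 0.0) -> float:
        w = np.asarray(w, dtype=float)
        var = float(w @ self.matrix @ w)
        if var <= 0 and ridge > 0:
            var = float(w @ (self.matrix + ridge * np.eye(len(w))) @ w)
        return float(np.sqrt(max(var, 0.0)))

    def subset(self, variant_ids: Sequence[str]) -> "ReferenceCovariance":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            idx = np.array([pos[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise DataError(f"variant {exc.args[0]!r} absent from covariance") from exc
        return ReferenceCovariance(list(variant_ids), self.matrix[np.ix_(idx, idx)])


@dataclass
class TwasResult:
    """Gene-level association result for one feature."""

    feature_id: str
    layer: str
    z: float
    p: float
    n_used: int
    n_dropped: int
    weight_mass_dropped: float = 0.0
    skipped: bool = False
    skip_reason: str = ""

    @staticmethod
    def frame(results: Iterable["TwasResult"]) -> pd.DataFrame:
        rows = [
            {
                "layer": r.layer, "feature_id": r.feature_id, "z": r.z, "p": r.p,
                "n_used": r.n_used, "n_dropped": r.n_dropped,
                "weight_mass_dropped": r.weight_mass_dropped,
                "skipped": r.skipped, "skip_reason": r.skip_reason,
            }
            for r in results
        ]
        return pd.DataFrame(rows)
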