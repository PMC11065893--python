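"""Gene-level association from GWAS summary statistics.

The gene-level statistic aggregates per-variant GWAS z-scores through the
prediction-model weights,

    Z_g = sum_{l in model_g} w_lg * (sigma_l / sigma_g) * (beta_l / se_l)

where sigma_l is the reference-panel SD of variant l's dosage and
sigma_g = sqrt(w' Gamma w) the SD of the predicted level, with Gamma the
reference-panel covariance of the model's variants (the S-PrediXcan
statistic).  Model variants absent from the GWAS are dropped and sigma_g is
recomputed on the intersection; models losing more than half their absolute
weight mass are flagged.  Per layer, m = number of models actually tested
and the Bonferroni threshold is 0.05/m.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    DataError,
    GenotypeMatrix,
    GwasSummaryStats,
    ReferenceCovariance,
    TwasResult,
    WeightDB,
    WeightModel,
)
from .qc import harmonize_alleles

GWAS_SIGNIFICANCE = 5e-8


def snp_covariance(
    panel: GenotypeMatrix, variant_ids: list[str]
) -> ReferenceCovariance:
    """Sample covariance (denominator n-1) of mean-centered panel dosages.

    Zero-variance variants are dropped with a warning; an empty result is
    an error.
    """
    X = panel.mean_imputed()[:, panel.index_of(variant_ids)]
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variant_ids, keep) if not k]
        warnings.warn(f"zero-variance variants dropped from covariance: {dropped[:5]}")
    ids = [v for v, k in zip(variant_ids, keep) if k]
    if not ids:
        raise DataError("no variants with nonzero variance remain")
    X = X[:, keep]
    gamma = np.cov(X, rowvar=False, ddof=1)
    gamma = np.atleast_2d(gamma)
    return ReferenceCovariance(ids, gamma)


def twas_zscore(
    model: WeightModel,
    stats: GwasSummaryStats,
    cov: ReferenceCovariance,
    ridge: float = 1e-8,
) -> TwasResult:
    """The summary-statistic gene-level Z for one weight model.

    Computed over the intersection of model variants, GWAS variants and the
    reference covariance; two-sided p from the standard normal.  An empty
    intersection or sigma_g = 0 yields a skipped result with the reason
    recorded.
    """
    st = stats.indexed()
    wtab = model.weights
    total_mass = float(np.abs(wtab["weight"]).sum())
    in_gwas = wtab["variant_id"].isin(st.index)
    in_cov = wtab["variant_id"].isin(cov.variant_ids)
    usable = wtab[in_gwas & in_cov]
    n_dropped = len(wtab) - len(usable)
    if len(usable) == 0:
        return TwasResult(model.feature_id, model.layer, float("nan"), float("nan"),
                          0, n_dropped, 1.0, skipped=True,
                          skip_reason="no model variants in GWAS")
    sub = cov.subset(list(usable["variant_id"]))
    w = usable["weight"].to_numpy()
    sigma_l = sub.sigma
    sigma_g = sub.sigma_g(w, ridge=ridge)
    if sigma_g == 0:
        return TwasResult(model.feature_id, model.layer, float("nan"), float("nan"),
                          len(usable), n_dropped, skipped=True,
                          skip_reason="sigma_g is zero")
    rows = st.loc[usable["variant_id"]]
    z_l = rows["beta"].to_numpy() / rows["se"].to_numpy()
    z = float(np.sum(w * sigma_l * z_l) / sigma_g)
    p = float(2.0 * sps.norm.sf(abs(z)))
    mass_dropped = 1.0 - float(np.abs(w).sum()) / total_mass if total_mass > 0 else 0.0
    res = TwasResult(model.feature_id, model.layer, z, p, len(usable), n_dropped,
                     weight_mass_dropped=mass_dropped)
    if mass_dropped > 0.5:
        warnings.warn(
            f"{model.layer}/{model.feature_id}: >50% of weight mass missing from GWAS"
        )
    return res


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance cutoff alpha/m for m tests."""
    if m <= 0:
        raise DataError("number of tests must be positive")
    return alpha / m


def twas_scan(
    db: WeightDB,
    stats: GwasSummaryStats,
    panel: GenotypeMatrix,
    harmonize: bool = True,
) -> pd.DataFrame:
    """Run the gene-level test for every retained model, per layer.

    Returns one row per model with z, p, per-layer test count m, the
    Bonferroni threshold 0.05/m, and the significance flag.  Features that
    are untestable (no GWAS overlap, zero sigma_g) are kept in the output
    with skipped=True but excluded from m.
    """
    if len(db) == 0:
        raise DataError("empty weight database")
    all_model_variants = (
        pd.concat([m.weights for m in db.models.values()])
        .drop_duplicates("variant_id")[["variant_id", "effect_allele", "other_allele"]]
        .reset_index(drop=True)
    )
    if harmonize:
        stats, _ = harmonize_alleles(all_model_variants, stats)
    frames = []
    for layer in db.layers:
        results = []
        for model in db.per_layer(layer):
            present = model.weights["variant_id"][
                model.weights["variant_id"].isin(panel.variants["variant_id"])
            ]
            if len(present) == 0:
                results.append(TwasResult(model.feature_id, layer, float("nan"),
                                          float("nan"), 0, len(model.weights), 1.0,
                                          skipped=True,
                                          skip_reason="no model variants in panel"))
                continue
            cov = snp_covariance(panel, list(present))
            results.append(twas_zscore(model, stats, cov))
        frame = TwasResult.frame(results)
        m_tested = int((~frame["skipped"]).sum())
        frame["m"] = m_tested
        frame["threshold"] = bonferroni_threshold(m_tested) if m_tested else np.nan
        frame["significant"] = (~frame["skipped"]) & (frame["p"] < frame["threshold"])
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["layer", "feature_id"]).reset_index(drop=True)


def replication_test(z: float, prior_direction: int) -> float:
    """One-sided replication p in the direction a prior study reported.

    p = Phi(-z * direction): small when the new Z lands on the previously
    reported side; replicated at p < 0.05.
    """
    if prior_direction not in (1, -1):
        raise DataError("prior_direction must be +1 or -1")
    return float(sps.norm.sf(z * prior_direction))


def zscore_from_p(p: float, sign: int = 1, one_sided: bool = False) -> float:
    """Invert a printed p-value to the |Z| (or signed Z) that produced it."""
    if not (0 < p < 1):
        raise DataError("p must lie in (0, 1)")
    z = sps.norm.isf(p if one_sided else p / 2.0)
    return float(sign * z)
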