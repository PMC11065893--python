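"""Quantification, filtering, normalization and covariate construction for
the three molecular phenotype layers.

Processing mirrors the GTEx-style expression pipeline: expression is
filtered on a 5% detection rate and log2(TPM+1)-transformed; APA (PDUI) and
junction (PSI) events are filtered on a 5% missingness rate with surviving
missing values median-imputed; all layers are quantile-normalized across
samples; hidden structure is captured by principal-component latent factors
(a deterministic surrogate for PEER); features are residualized on the full
covariate block before model training.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    CovariateMatrix,
    DataError,
    MolecularPhenotypeMatrix,
)


def expression_filter_and_transform(
    tpm: MolecularPhenotypeMatrix, detection_fraction: float = 0.05
) -> MolecularPhenotypeMatrix:
    """Drop genes detected (TPM > 0) in <= 5% of samples; log2(TPM+1) the rest.

    The pseudocount of 1 keeps zeros at zero on the log scale.
    """
    if tpm.layer != "expression":
        raise DataError("expression_filter_and_transform expects the expression layer")
    vals = tpm.values
    expressed_frac = (vals > 0).mean(axis=1)
    kept = vals.loc[expressed_frac > detection_fraction]
    return tpm.with_values(np.log2(kept + 1.0), transformed=True)


def event_missingness_filter(
    m: MolecularPhenotypeMatrix, max_missing: float = 0.05
) -> MolecularPhenotypeMatrix:
    """Drop APA/junction events with > 5% missing values; median-impute the rest."""
    if m.layer not in ("apa", "junction"):
        raise DataError("event_missingness_filter expects the apa or junction layer")
    vals = m.values
    missing_frac = vals.isna().mean(axis=1)
    kept = vals.loc[missing_frac <= max_missing].copy()
    medians = kept.median(axis=1)
    kept = kept.T.fillna(medians).T
    return m.with_values(kept)


def quantile_normalize(
    m: MolecularPhenotypeMatrix, dialect: str = "cross_sample"
) -> MolecularPhenotypeMatrix:
    """Force every sample onto a common distribution.

    ``cross_sample`` (default) is the classic rank-mean recipe: each
    sample's sorted values are replaced by the per-rank mean over samples,
    ties resolved by average rank.  ``inverse_normal`` instead maps each
    feature to rank-based normal scores (the GTEx per-feature dialect).
    """
    vals = m.values
    if vals.isna().any().any():
        raise DataError("quantile_normalize requires complete data (filter/impute first)")
    arr = vals.to_numpy(dtype=float)
    n_feat, n_samp = arr.shape
    if dialect == "inverse_normal":
        out = np.empty_like(arr)
        for i in range(n_feat):
            ranks = sps.rankdata(arr[i])
            out[i] = sps.norm.ppf(ranks / (n_samp + 1))
        return m.with_values(pd.DataFrame(out, index=vals.index, columns=vals.columns),
                             transformed=True)
    if dialect != "cross_sample":
        raise DataError(f"unknown quantile normalization dialect {dialect!r}")
    if n_samp == 1:
        return m.with_values(vals.copy())
    reference = np.sort(arr, axis=0).mean(axis=1)  # per-rank mean over samples
    out = np.empty_like(arr)
    grid = np.arange(n_feat, dtype=float)
    for j in range(n_samp):
        ranks = sps.rankdata(arr[:, j]) - 1.0  # 0-based, ties -> average rank
        out[:, j] = np.interp(ranks, grid, reference)
    normd = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return m.with_values(normd, transformed=True)


def infer_latent_factors(
    m: MolecularPhenotypeMatrix, k: int | None = None
) -> CovariateMatrix:
    """Top-k principal-component scores of the feature-standardized matrix.

    Deterministic surrogate for PEER latent confounders.  ``k`` defaults to
    15 for n < 150 samples and 30 otherwise (the GTEx sample-size rule).
    Sign is fixed by making each factor's largest-|loading| entry positive.
    """
    vals = m.values
    if vals.isna().any().any():
        raise DataError("infer_latent_factors requires complete data")
    n_samp = vals.shape[1]
    if k is None:
        k = 15 if n_samp < 150 else 30
    if k >= n_samp:
        raise DataError(f"k={k} must be smaller than the number of samples ({n_samp})")
    if k == 0:
        return CovariateMatrix(pd.DataFrame(index=vals.columns))
    X = vals.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    for j in range(k):  # deterministic sign convention
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    table = pd.DataFrame(scores, index=vals.columns,
                         columns=[f"factor_{i + 1}" for i in range(k)])
    return CovariateMatrix(table)


def combine_covariates(*blocks: CovariateMatrix | pd.DataFrame) -> CovariateMatrix:
    """Column-concatenate covariate blocks (age, genotype PCs, latent factors)."""
    frames = [b.table if isinstance(b, CovariateMatrix) else b for b in blocks]
    frames = [f for f in frames if f.shape[1] > 0]
    if not frames:
        raise DataError("no covariate columns supplied")
    table = pd.concat(frames, axis=1)
    if table.isna().any().any():
        raise DataError("covariate blocks do not share a complete sample set")
    return CovariateMatrix(table)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank == design.shape[1]:
        return
    # identify offending columns greedily so the error is actionable
    colnames = ["intercept"] + list(names)
    bad = []
    cols: list[int] = []
    for j in range(design.shape[1]):
        trial = design[:, cols + [j]]
        if np.linalg.matrix_rank(trial) == len(cols) + 1:
            cols.append(j)
        else:
            bad.append(colnames[j])
    raise DataError(f"rank-deficient covariates; collinear column(s): {', '.join(bad)}")


def residualize(
    m: MolecularPhenotypeMatrix, cov: CovariateMatrix
) -> MolecularPhenotypeMatrix:
    """Replace each feature by its least-squares residual on [1 | covariates].

    Residuals are orthogonal to every covariate; applying the operation
    twice equals applying it once.
    """
    vals = m.values
    if vals.isna().any().any():
        raise DataError("residualize requires complete data")
    samples = list(vals.columns)
    C = cov.table.reindex(samples)
    if C.isna().any().any():
        raise DataError("covariates missing for some phenotype samples")
    design = np.column_stack([np.ones(len(samples)), C.to_numpy(dtype=float)])
    _check_full_rank(design, cov.names)
    Y = vals.to_numpy(dtype=float).T  # samples x features
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = (Y - design @ coef).T
    return m.with_values(pd.DataFrame(resid, index=vals.index, columns=vals.columns),
                         transformed=True)


def _ratio_phenotype(
    numer: pd.DataFrame,
    denom_other: pd.DataFrame,
    anchors: pd.DataFrame,
    layer: str,
    min_depth: int,
) -> MolecularPhenotypeMatrix:
    if (numer < 0).any().any() or (denom_other < 0).any().any():
        raise DataError("read counts must be non-negative")
    if not numer.index.equals(denom_other.index) or not numer.columns.equals(denom_other.columns):
        raise DataError("count tables must share features and samples")
    totals = numer + denom_other
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = numer / totals
    ratio = ratio.where(totals >= min_depth)
    return MolecularPhenotypeMatrix(layer=layer, values=ratio, anchors=anchors)


def quantify_pdui(
    proximal_counts: pd.DataFrame,
    distal_counts: pd.DataFrame,
    anchors: pd.DataFrame,
    min_depth: int = 10,
) -> MolecularPhenotypeMatrix:
    """PDUI = distal / (proximal + distal); totals below min_depth are missing."""
    return _ratio_phenotype(distal_counts, proximal_counts, anchors, "apa", min_depth)


def quantify_psi(
    inclusion_counts: pd.DataFrame,
    exclusion_counts: pd.DataFrame,
    anchors: pd.DataFrame,
    min_depth: int = 10,
) -> MolecularPhenotypeMatrix:
    """PSI = inclusion / (inclusion + exclusion); totals below min_depth are missing."""
    return _ratio_phenotype(inclusion_counts, exclusion_counts, anchors, "junction", min_depth)


def prepare_layer(
    m: MolecularPhenotypeMatrix,
    covariates: CovariateMatrix | None = None,
    n_factors: int | None = None,
    qn_dialect: str = "cross_sample",
) -> tuple[MolecularPhenotypeMatrix, CovariateMatrix]:
    """Full preparation chain for one layer.

    Filter -> quantile-normalize -> infer latent factors -> residualize on
    [supplied covariates | latent factors].  Returns the residualized
    matrix and the covariate block used.
    """
    if m.layer == "expression":
        filtered = expression_filter_and_transform(m) if not m.is_transformed else m
    else:
        filtered = event_missingness_filter(m)
    if len(filtered.values) > 1:
        normed = quantile_normalize(filtered, dialect=qn_dialect)
    else:
        # cross-sample quantile normalization is degenerate for a single
        # feature (every sample would collapse to the grand mean)
        normed = filtered

    factors = infer_latent_factors(normed, k=n_factors)
    blocks = [b for b in (covariates, factors) if b is not None and b.table.shape[1] > 0]
    if not blocks:
        cov = CovariateMatrix(pd.DataFrame(index=normed.values.columns))
        centered = normed.values.sub(normed.values.mean(axis=1), axis=0)
        return normed.with_values(centered), cov
    cov = combine_covariates(*blocks)
    return residualize(normed, cov), cov
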