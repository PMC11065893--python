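"""Per-feature cis elastic-net prediction models and the weight database.

For each molecular feature, every QC-passing variant within +/-500 kb of
the feature's anchor is offered to an elastic net (alpha = 0.5, i.e. equal
L1/L2 mixing) fit on the covariate-residualized phenotype.  The penalty
objective is

    (1/2n) ||y - Xw - b||^2 + lambda * (alpha * ||w||_1 + (1-alpha)/2 * ||w||_2^2)

with lambda chosen by 5-fold cross-validation over a 100-point log grid
descending four orders of magnitude from lambda_max (the glmnet lambda.min
rule).  The cross-validated prediction R — the signed Pearson correlation
between held-out fold predictions at lambda.min and the observed phenotype
— is the retention statistic: models with R > 0.1 (strict) and at least one
non-zero weight enter the weight database.

Genotype columns are standardized internally for fitting; exported weights
are rescaled so they apply to raw 0-2 dosages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .containers import (
    DataError,
    GenotypeMatrix,
    MolecularPhenotypeMatrix,
    WeightDB,
    WeightModel,
)

DEFAULT_CIS_WINDOW = 500_000


def select_cis_variants(
    anchor: pd.Series, variants: pd.DataFrame, window: int = DEFAULT_CIS_WINDOW
) -> pd.DataFrame:
    """Variants within [start - window, end + window] (inclusive, floored at 1)."""
    lo = max(1, int(anchor["start"]) - window)
    hi = int(anchor["end"]) + window
    mask = (
        (variants["chrom"].astype(str) == str(anchor["chrom"]))
        & (variants["pos"] >= lo)
        & (variants["pos"] <= hi)
    )
    return variants[mask]


@dataclass
class ElasticNetFit:
    weights: np.ndarray
    intercept: float
    lambda_: float
    cv_r: float = float("nan")
    cv_pred: np.ndarray | None = None

    @property
    def n_nonzero(self) -> int:
        return int((self.weights != 0).sum())


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, l1_ratio: float,
                 n_lambda: int, min_ratio: float) -> np.ndarray:
    n = len(yc)
    lmax = np.abs(Xs.T @ yc).max() / (n * max(l1_ratio, 1e-3))
    lmax = max(lmax, 1e-12)
    return np.logspace(np.log10(lmax), np.log10(lmax * min_ratio), n_lambda)


def _cv_path(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float,
    n_lambda: int,
    min_ratio: float,
    k: int,
    seed: int,
) -> tuple[np.ndarray, int, np.ndarray, float]:
    """Fold-held-out predictions along the lambda path (cv.glmnet convention).

    Returns (lambda grid, index of lambda.min, held-out predictions at
    lambda.min, cross-validated prediction R).
    """
    n = len(y)
    Xs_full, _, _ = _standardize(X)
    alphas = _lambda_grid(Xs_full, y - y.mean(), l1_ratio, n_lambda, min_ratio)
    preds = np.empty((n, len(alphas)))
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    # held-out predictions carry the global mean rather than each fold's
    # training mean: fold-mean intercepts anti-correlate with the held-out
    # outcomes and would bias the null cv R negative
    y_mean = y.mean()
    for train, test in kf.split(X):
        Xtr, mu, sd = _standardize(X[train])
        ym = y[train].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = enet_path(Xtr, y[train] - ym, l1_ratio=l1_ratio,
                                    alphas=alphas)
        preds[test] = ((X[test] - mu) / sd) @ coefs + y_mean
    mse = ((preds - y[:, None]) ** 2).mean(axis=0)
    best = int(np.argmin(mse))
    cv_pred = preds[:, best]
    if cv_pred.std() == 0 or y.std() == 0:
        cv_r = 0.0
    else:
        cv_r = float(np.corrcoef(cv_pred, y)[0, 1])
    return alphas, best, cv_pred, cv_r


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    lambda_: float | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    cv: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> ElasticNetFit:
    """Fit the elastic net; lambda by inner CV unless given explicitly.

    Returned weights are on the original dosage scale.  ``standardize=False``
    skips the internal column scaling (useful for closed-form checks on
    pre-scaled designs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise DataError("X must have at least one column")
    if np.isnan(y).any():
        raise DataError("phenotype must be complete")
    if y.std() == 0:
        raise DataError("zero-variance phenotype")

    cv_r = float("nan")
    cv_pred = None
    if lambda_ is None:
        _, best, cv_pred, cv_r = _cv_path(
            X, y, alpha, n_lambda, lambda_min_ratio, cv, seed
        )
        alphas = _lambda_grid(_standardize(X)[0], y - y.mean(), alpha,
                              n_lambda, lambda_min_ratio)
        lambda_ = float(alphas[best])

    if standardize:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    ym = y.mean()
    model = ElasticNet(alpha=lambda_, l1_ratio=alpha, fit_intercept=False,
                       max_iter=5000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y - ym)
    w = model.coef_ / sd
    intercept = float(ym - w @ mu)
    return ElasticNetFit(weights=w, intercept=intercept, lambda_=float(lambda_),
                         cv_r=cv_r, cv_pred=cv_pred)


def cross_validated_performance(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> float:
    """Cross-validated prediction R at lambda.min.

    Samples are split into k seeded, disjoint folds; held-out predictions
    are concatenated and correlated with the observed phenotype.  Constant
    predictions give R = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise DataError(f"need at least k={k} samples for {k}-fold CV")
    _, _, _, cv_r = _cv_path(X, y, alpha, n_lambda, lambda_min_ratio, k, seed)
    return cv_r


def train_feature_models(
    panel: GenotypeMatrix,
    phenotypes: MolecularPhenotypeMatrix,
    cis_window: int = DEFAULT_CIS_WINDOW,
    alpha: float = 0.5,
    folds: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> list[WeightModel]:
    """Train one elastic-net model per feature of a residualized layer.

    The phenotype matrix must already be residualized on covariates.
    Features with an empty cis window are skipped with a warning.  The
    weight table of each model keeps only non-zero weights; the model's
    effect allele is the panel's alternate allele (whose dosage the weight
    multiplies).
    """
    if list(phenotypes.samples) != list(panel.samples):
        raise DataError("phenotype samples must match panel samples (same order)")
    X_all = panel.mean_imputed()
    models: list[WeightModel] = []
    for fid in phenotypes.feature_ids:
        anchor = phenotypes.anchors.loc[fid]
        cis = select_cis_variants(anchor, panel.variants, cis_window)
        if len(cis) == 0:
            warnings.warn(f"feature {fid}: no cis variants, skipped")
            continue
        X = X_all[:, cis.index.to_numpy()]
        y = phenotypes.values.loc[fid].to_numpy(dtype=float)
        if y.std() == 0:
            warnings.warn(f"feature {fid}: constant phenotype, skipped")
            continue
        fit = fit_elastic_net(X, y, alpha=alpha, cv=folds, seed=seed,
                              n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
        nz = np.flatnonzero(fit.weights)
        wtab = pd.DataFrame(
            {
                "variant_id": cis["variant_id"].to_numpy()[nz],
                "chrom": cis["chrom"].to_numpy()[nz],
                "pos": cis["pos"].to_numpy()[nz],
                "effect_allele": cis["alt"].to_numpy()[nz],
                "other_allele": cis["ref"].to_numpy()[nz],
                "weight": fit.weights[nz],
            }
        )
        models.append(
            WeightModel(
                feature_id=fid,
                layer=phenotypes.layer,
                weights=wtab,
                cv_r=fit.cv_r,
                lambda_=fit.lambda_,
                n_folds=folds,
                seed=seed,
            )
        )
    return models


def predict_feature(model: WeightModel, geno: GenotypeMatrix) -> np.ndarray:
    """Genetically predicted level (GReX) of a feature for each sample."""
    if model.n_nonzero == 0:
        return np.zeros(geno.n_samples)
    X = geno.dosage_for(list(model.weights["variant_id"]))
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        r, c = np.nonzero(np.isnan(X))
        X[r, c] = col_means[c]
    return X @ model.weights["weight"].to_numpy()


def build_weight_db(
    models: list[WeightModel],
    r_threshold: float = 0.1,
    attempted: dict[str, int] | None = None,
) -> WeightDB:
    """Retain models with cv R strictly above threshold and >= 1 non-zero weight.

    ``counts`` per layer record the model-building funnel: attempted
    (defaults to the number of models offered for that layer), predictable
    (>= 1 non-zero weight), retained (also cv R > threshold).
    """
    db = WeightDB(r_threshold=r_threshold)
    tallies: dict[str, dict[str, int]] = {}
    for m in models:
        t = tallies.setdefault(m.layer, {"attempted": 0, "predictable": 0, "retained": 0})
        t["attempted"] += 1
        if m.n_nonzero >= 1:
            t["predictable"] += 1
            if m.cv_r > r_threshold:
                t["retained"] += 1
                db.add(m.nonzero())
    if attempted:
        for layer, n in attempted.items():
            tallies.setdefault(layer, {"attempted": 0, "predictable": 0, "retained": 0})
            tallies[layer]["attempted"] = n
    db.counts = tallies
    return db
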