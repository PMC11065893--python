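"""Approximate conditional analysis on summary statistics and the
weight-permutation test.

Conditional analysis follows the summary-statistic (COJO-style) algebra:
with D_j = n * Gamma_jj approximating the j-th diagonal of X'X and
B_jk = n * Gamma_jk its off-diagonals (Gamma from the reference panel), the
joint effect of the conditioning set C is

    b_C = B_CC^{-1} (D_C o beta_C)

and the effect of a target variant t adjusted for C is

    beta~_t = beta_t - D_t^{-1} B_tC b_C ,   se(beta~_t) = sqrt(sigma^2 / D_t)

with the phenotypic variance sigma^2 treated as fixed (1 for a
standardized trait).  For case-control GWAS the same algebra is applied on
the log-odds scale, which is an approximation.  A feature's TWAS statistic
is then recomputed from the adjusted statistics (same weights, same
reference variances).

The permutation test shuffles the weight-to-variant assignment within a
model (the FUSION convention) and asks how often the permuted |Z| reaches
the observed one: empirical p = (1 + #exceedances) / (1 + #permutations),
with a cap of 1000 permutations, an entry threshold of 0.05 on the marginal
TWAS p, and adaptive early stopping once 20 exceedances are seen.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import GWAS_SIGNIFICANCE, twas_zscore
from .containers import (
    DataError,
    GenotypeMatrix,
    GwasSummaryStats,
    ReferenceCovariance,
    TwasResult,
    WeightModel,
)


@dataclass
class ConditionalResult:
    """Conditional rerun of the gene-level test for one feature."""

    feature_id: str
    layer: str
    conditioning_variants: list[str]
    marginal: TwasResult
    conditional: TwasResult | None
    conditioned: bool

    @property
    def z(self) -> float:
        return self.conditional.z if self.conditioned else self.marginal.z

    @property
    def p(self) -> float:
        return self.conditional.p if self.conditioned else self.marginal.p


@dataclass
class PermutationResult:
    feature_id: str
    layer: str
    n_permutations: int
    n_exceedances: int
    p: float
    seed: int
    evaluable: bool = True
    reason: str = ""


def conditional_summary_stats(
    stats: GwasSummaryStats,
    cond_ids: list[str],
    cov: ReferenceCovariance,
    n: int,
    var_pheno: float = 1.0,
) -> GwasSummaryStats:
    """Adjust marginal effects for a set of conditioning variants.

    Every variant present in both ``stats`` and ``cov`` gets an adjusted
    beta and se; variants uncorrelated with the conditioning set are left
    numerically unchanged, and a variant conditioned on itself goes to
    exactly zero.  Variants outside ``cov`` pass through untouched.
    """
    if not cond_ids:
        raise DataError("conditioning set is empty")
    st = stats.indexed()
    missing = [v for v in cond_ids if v not in st.index or v not in cov.variant_ids]
    if missing:
        raise DataError(f"conditioning variants absent from stats/covariance: {missing}")
    if n <= len(cond_ids) + 1:
        raise DataError("sample size too small for the conditioning set")

    ids = [v for v in cov.variant_ids if v in st.index]
    sub = cov.subset(ids)
    B = n * sub.matrix
    D = np.diag(B).copy()
    if (D <= 0).any():
        raise DataError("conditioning requires nonzero variance for every variant")
    pos = {v: i for i, v in enumerate(ids)}
    c_idx = np.array([pos[v] for v in cond_ids], dtype=int)
    beta = st.loc[ids, "beta"].to_numpy()
    B_cc = B[np.ix_(c_idx, c_idx)]
    rhs = D[c_idx] * beta[c_idx]
    try:
        b_c = np.linalg.solve(B_cc, rhs)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            "singular LD matrix among conditioning variants; prune the set"
        ) from exc
    adj_beta = beta - (B[:, c_idx] @ b_c) / D
    adj_se = np.sqrt(var_pheno / D)
    adj_p = 2.0 * sps.norm.sf(np.abs(adj_beta / adj_se))

    table = stats.table.copy().set_index("variant_id", drop=False)
    table.loc[ids, "beta"] = adj_beta
    table.loc[ids, "se"] = adj_se
    table.loc[ids, "p"] = adj_p
    return GwasSummaryStats(table.reset_index(drop=True))


def find_lead_variant(
    anchor: pd.Series,
    stats: GwasSummaryStats,
    window: int = 500_000,
    significance: float = GWAS_SIGNIFICANCE,
) -> str | None:
    """Nearest GWAS-significant variant within +/-window of the anchor.

    Distance is to the anchor interval; ties are broken by the smaller p.
    Returns None when no variant in the window reaches significance.
    """
    t = stats.table
    lo = max(1, int(anchor["start"]) - window)
    hi = int(anchor["end"]) + window
    cand = t[
        (t["chrom"].astype(str) == str(anchor["chrom"]))
        & (t["pos"] >= lo) & (t["pos"] <= hi)
        & (t["p"] < significance)
    ]
    if len(cand) == 0:
        return None
    dist = np.maximum(
        anchor["start"] - cand["pos"], cand["pos"] - anchor["end"]
    ).clip(lower=0)
    order = pd.DataFrame({"dist": dist, "p": cand["p"], "vid": cand["variant_id"]})
    order = order.sort_values(["dist", "p"], kind="mergesort")
    return str(order["vid"].iloc[0])


def conditional_twas(
    model: WeightModel,
    anchor: pd.Series,
    stats: GwasSummaryStats,
    panel: GenotypeMatrix,
    n_gwas: int,
    window: int = 500_000,
    significance: float = GWAS_SIGNIFICANCE,
    var_pheno: float = 1.0,
    lead_variant: str | None = None,
) -> ConditionalResult:
    """Rerun the gene-level test after adjusting for the nearest lead variant.

    When no GWAS-significant variant lies within the window the marginal
    result is returned flagged as not conditioned.
    """
    from .association import snp_covariance

    model_ids = [v for v in model.weights["variant_id"]
                 if v in set(panel.variants["variant_id"])]
    if not model_ids:
        raise DataError(f"model {model.feature_id}: no variants in panel")
    cov_model = snp_covariance(panel, model_ids)
    marginal = twas_zscore(model, stats, cov_model)

    if lead_variant is None:
        lead_variant = find_lead_variant(anchor, stats, window, significance)
    if lead_variant is None or lead_variant not in set(stats.table["variant_id"]):
        return ConditionalResult(model.feature_id, model.layer, [], marginal,
                                 None, conditioned=False)
    union = list(dict.fromkeys(model_ids + [lead_variant]))
    cov_union = snp_covariance(panel, union)
    adj = conditional_summary_stats(stats, [lead_variant], cov_union,
                                    n=n_gwas, var_pheno=var_pheno)
    conditional = twas_zscore(model, adj, cov_model)
    return ConditionalResult(model.feature_id, model.layer, [lead_variant],
                             marginal, conditional, conditioned=True)


def permutation_test(
    model: WeightModel,
    stats: GwasSummaryStats,
    cov: ReferenceCovariance,
    max_perm: int = 1000,
    entry_threshold: float = 0.05,
    early_stop_exceedances: int | None = 20,
    seed: int = 0,
    scheme: str = "shuffle",
    batch: int = 100,
) -> PermutationResult:
    """Empirical p for the observed |Z| against weight-permuted models.

    ``scheme='shuffle'`` permutes the weight-to-variant assignment within
    the model; ``'signflip'`` flips each weight's sign independently.
    Models with fewer than 3 variants, or with a marginal p at or above the
    entry threshold, are reported as not evaluable / skipped.
    """
    observed = twas_zscore(model, stats, cov)
    if observed.skipped or not np.isfinite(observed.z):
        return PermutationResult(model.feature_id, model.layer, 0, 0, float("nan"),
                                 seed, evaluable=False, reason=observed.skip_reason)
    if entry_threshold < 1.0 and observed.p >= entry_threshold:
        return PermutationResult(model.feature_id, model.layer, 0, 0, float("nan"),
                                 seed, evaluable=False,
                                 reason=f"marginal p {observed.p:.3g} above entry threshold")
    st = stats.indexed()
    usable = model.weights[
        model.weights["variant_id"].isin(st.index)
        & model.weights["variant_id"].isin(cov.variant_ids)
    ]
    k = len(usable)
    if k < 3:
        return PermutationResult(model.feature_id, model.layer, 0, 0, float("nan"),
                                 seed, evaluable=False, reason="fewer than 3 variants")
    sub = cov.subset(list(usable["variant_id"]))
    w = usable["weight"].to_numpy()
    sigma_l = sub.sigma
    z_l = (st.loc[usable["variant_id"], "beta"]
           / st.loc[usable["variant_id"], "se"]).to_numpy()
    score = sigma_l * z_l
    gamma = sub.matrix
    z_obs = abs(observed.z)

    rng = np.random.default_rng(seed)
    n_done = 0
    n_exc = 0
    while n_done < max_perm:
        b = min(batch, max_perm - n_done)
        if scheme == "shuffle":
            W = np.empty((b, k))
            for i in range(b):
                W[i] = w[rng.permutation(k)]
        elif scheme == "signflip":
            W = w[None, :] * rng.choice([-1.0, 1.0], size=(b, k))
        else:
            raise DataError(f"unknown permutation scheme {scheme!r}")
        num = W @ score
        var_g = np.einsum("bi,ij,bj->b", W, gamma, W)
        ok = var_g > 0
        z_perm = np.zeros(b)
        z_perm[ok] = num[ok] / np.sqrt(var_g[ok])
        n_exc += int((np.abs(z_perm) >= z_obs).sum())
        n_done += b
        if early_stop_exceedances is not None and n_exc >= early_stop_exceedances:
            break
    p = (1.0 + n_exc) / (1.0 + n_done)
    return PermutationResult(model.feature_id, model.layer, n_done, n_exc, p, seed)
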