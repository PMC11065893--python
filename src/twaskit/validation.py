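"""Simulation studies that validate the pipeline end to end.

Each study rebuilds its inputs from the synthetic cohort generator at a
fixed seed, runs the relevant pipeline stages, and measures the property of
interest against an independent oracle (individual-level regression,
exhaustive enumeration) or a known null.  Study sizes are chosen so the
whole battery runs in a few minutes on one CPU; docs/methods.md records
them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import snp_covariance, twas_scan
from .conditional import conditional_summary_stats, conditional_twas, permutation_test
from .containers import GwasSummaryStats
from .models import build_weight_db, predict_feature, train_feature_models
from .phenotypes import prepare_layer
from .synthetic import (
    SimulationConfig,
    genetic_values,
    simulate_gwas_summary_stats,
    simulate_ld_genotypes,
    simulate_molecular_phenotypes,
)


def _train_layer(panel, config, layer="expression", seed=0):
    """Simulate one phenotype layer on the panel and train its models.

    Latent factors need many features to be meaningful; small loci are
    adjusted for the simulated covariates only.
    """
    pheno, truth = simulate_molecular_phenotypes(panel, config, layer)
    from .containers import CovariateMatrix

    cov = CovariateMatrix(truth.covariates)
    n_factors = 5 if config.n_features >= 20 else 0
    resid, _ = prepare_layer(pheno, covariates=cov, n_factors=n_factors)
    models = train_feature_models(panel, resid, cis_window=config.cis_window,
                                  seed=seed)
    return models, truth, resid


def oracle_equivalence_study(
    seed: int = 0, n: int = 2000, n_features: int = 50
) -> pd.DataFrame:
    """Summary-based Z versus individual-level predicted-level regression z.

    The reference panel IS the GWAS cohort (full overlap) and the trait is
    the continuous liability, the setting in which the summary statistic is
    an algebraic approximation of the individual-level test.  Returns one
    row per retained model with both z-scores.
    """
    config = SimulationConfig(
        n_ref_samples=n, n_gwas_samples=n, n_variants=n_features * 30,
        chrom_length=n_features * 1_000_000, n_features=n_features,
        cis_h2=0.3, n_causal_per_feature=2, ld_rho=0.7, seed=seed,
    )
    panel, _ = simulate_ld_genotypes(config, stream=0)
    models, truth, resid = _train_layer(panel, config, seed=seed)
    # half of the features mediate a modest liability effect
    alphas = {m.feature_id: (0.06 if i % 2 == 0 else 0.0)
              for i, m in enumerate(models)}
    truth.alpha.update(alphas)
    stats = simulate_gwas_summary_stats(panel, truth, config, mode="linear")
    db = build_weight_db(models)

    # reconstruct the continuous trait exactly as the generator drew it
    liability = _reconstruct_liability(panel, truth, config)
    rows = []
    scan = twas_scan(db, stats, panel).set_index("feature_id")
    for model in db.models.values():
        grex = predict_feature(model, panel)
        if grex.std() == 0:
            continue
        sl, inter, r, _, _ = sps.linregress(grex, liability)
        t = r * np.sqrt((n - 2) / max(1 - r * r, 1e-12))
        rows.append({"feature_id": model.feature_id,
                     "z_summary": scan.loc[model.feature_id, "z"],
                     "z_individual": t})
    out = pd.DataFrame(rows)
    out["abs_dz"] = (out["z_summary"] - out["z_individual"]).abs()
    return out


def _reconstruct_liability(geno, truth, config):
    """Continuous liability exactly as simulate_gwas_summary_stats draws it."""
    rng = np.random.default_rng([config.seed, 505])
    n = geno.n_samples
    liability = np.zeros(n)
    alphas = {f: a for f, a in truth.alpha.items() if a != 0.0}
    var_gen = sum(a * a for a in alphas.values())
    if alphas:
        gvals = genetic_values(geno, truth, list(alphas))
        for fid, a in alphas.items():
            g = gvals[fid].to_numpy()
            sd = g.std()
            if sd > 0:
                liability += a * (g - g.mean()) / sd
    liability += rng.standard_normal(n) * np.sqrt(1.0 - var_gen)
    return liability


def conditional_oracle_study(seed: int = 0, n: int = 2000,
                             n_scenarios: int = 20) -> pd.DataFrame:
    """Conditional beta versus individual-level joint OLS.

    Full-overlap linear-trait setting.  Each scenario conditions a causal
    target variant on a variant far enough along the AR(1) chain that the
    conditional and joint estimands coincide (the conditional estimator is
    shrunk by 1 - r^2 relative to joint OLS by construction, so weak-LD
    pairs are the regime where both should agree).
    """
    rng = np.random.default_rng(seed)
    config = SimulationConfig(
        n_ref_samples=n, n_gwas_samples=n, n_variants=400,
        chrom_length=20_000_000, n_features=4, ld_rho=0.9, seed=seed,
    )
    panel, truth = simulate_ld_genotypes(config, stream=0)
    X = panel.mean_imputed()
    m = panel.n_variants

    # a handful of variants with direct liability effects
    causal_idx = rng.choice(m, size=8, replace=False)
    beta_true = rng.normal(0, 0.08, size=8)
    y = X[:, causal_idx] @ beta_true
    y = (y - y.mean()) + rng.standard_normal(n) * np.sqrt(max(1 - y.var(), 0.1))
    y = (y - y.mean()) / y.std()

    from .synthetic import _linear_scan

    beta, se, p = _linear_scan(X, y)
    vids = panel.variants["variant_id"].to_numpy()
    stats = GwasSummaryStats(pd.DataFrame({
        "variant_id": vids, "chrom": panel.variants["chrom"],
        "pos": panel.variants["pos"],
        "effect_allele": panel.variants["alt"], "other_allele": panel.variants["ref"],
        "eaf": X.mean(axis=0) / 2.0, "beta": beta, "se": se, "p": p, "n": n,
    }))

    rows = []
    for s in range(n_scenarios):
        t_idx = int(causal_idx[s % len(causal_idx)])
        # conditioning variant >= 40 AR(1) steps away: latent r ~ 0.9^40
        offset = 40 + int(rng.integers(0, 60))
        c_idx = t_idx + offset if t_idx + offset < m else t_idx - offset
        cov = snp_covariance(panel, [vids[t_idx], vids[c_idx]])
        adj = conditional_summary_stats(stats, [vids[c_idx]], cov, n=n)
        b_cond = adj.indexed().loc[vids[t_idx], "beta"]
        # individual-level joint OLS oracle
        design = np.column_stack([np.ones(n), X[:, t_idx], X[:, c_idx]])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        b_joint = coef[1]
        rows.append({"scenario": s, "b_conditional": b_cond, "b_joint": b_joint,
                     "rel_err": abs(b_cond - b_joint) / abs(b_joint)})
    return pd.DataFrame(rows)


@dataclass
class ConditionalBehavior:
    mediated_cond_abs_z: list = field(default_factory=list)
    mediated_marginal_abs_z: list = field(default_factory=list)
    independent_cond_p: list = field(default_factory=list)
    not_conditioned_flags: list = field(default_factory=list)

    @property
    def mediated_drop_rate(self) -> float:
        ok = [(c < 1.0) and (m > 4.0) for c, m in
              zip(self.mediated_cond_abs_z, self.mediated_marginal_abs_z)]
        return float(np.mean(ok))

    @property
    def independent_retain_rate(self) -> float:
        return float(np.mean([p < 1e-3 for p in self.independent_cond_p]))


def conditional_behavior_study(seed: int = 0, n_reps: int = 20) -> ConditionalBehavior:
    """Mediated versus independent signals under lead-variant conditioning.

    Mediated: the feature's sole causal cis variant is itself the GWAS lead
    variant, so conditioning should remove the gene-level signal (|Z| < 1).
    Independent: the feature's causal variant is in weak LD with a separate
    directly-associated lead variant, so the conditional signal survives
    (p < 1e-3).  Linear-trait GWAS for exact scale.
    """
    out = ConditionalBehavior()
    for rep in range(n_reps):
        # two features with non-overlapping cis windows ([0.5, 1.5] Mb and
        # [2.5, 3.5] Mb) so their causal variants are in weak LD
        config = SimulationConfig(
            n_ref_samples=800, n_gwas_samples=6000, n_variants=240,
            chrom_length=4_000_000, n_features=2, ld_rho=0.9,
            cis_h2=0.5, n_causal_per_feature=1, seed=seed + 1000 + rep,
        )
        panel, truth = simulate_ld_genotypes(config, stream=0)
        gwas, _ = simulate_ld_genotypes(config, n_samples=config.n_gwas_samples,
                                        stream=1, sample_prefix="gw")
        models, truth2, _ = _train_layer(panel, config, seed=config.seed)
        truth = truth.merge(truth2)
        if len(models) < 2:
            continue
        feat_a, feat_b = models[0].feature_id, models[1].feature_id
        lead_a = truth.causal_variants[feat_a]["variant_id"].iloc[0]

        # mediated: feature A drives liability entirely through its single
        # causal SNP, which is exactly the lead variant being conditioned on
        truth.alpha = {feat_a: 0.15}
        stats = simulate_gwas_summary_stats(gwas, truth, config, mode="linear")
        anchor = truth.features.loc[feat_a]
        res = conditional_twas(models[0], anchor, stats, panel,
                               n_gwas=config.n_gwas_samples, lead_variant=lead_a)
        if res.conditioned and not res.conditional.skipped:
            out.mediated_cond_abs_z.append(abs(res.conditional.z))
            out.mediated_marginal_abs_z.append(abs(res.marginal.z))

        # independent: feature B also drives liability; condition feature B's
        # signal on feature A's lead SNP (distant, weak LD)
        truth.alpha = {feat_a: 0.15, feat_b: 0.15}
        stats2 = simulate_gwas_summary_stats(gwas, truth, config, mode="linear")
        anchor_b = truth.features.loc[feat_b]
        res_b = conditional_twas(models[1], anchor_b, stats2, panel,
                                 n_gwas=config.n_gwas_samples, lead_variant=lead_a)
        if res_b.conditioned and not res_b.conditional.skipped:
            out.independent_cond_p.append(res_b.conditional.p)
        out.not_conditioned_flags.append(res.conditioned)
    return out


def null_calibration_study(
    seed: int = 0,
    n_features: int = 1200,
    block_features: int = 100,
    n_ref: int = 150,
    n_gwas: int = 3000,
) -> pd.DataFrame:
    """Gene-level p-values when no feature influences the trait.

    Features are simulated in independent LD blocks; models are trained on
    the reference panel as usual, and the case-control GWAS carries no
    genetic signal, so retained models' p-values should be uniform.
    """
    blocks = int(np.ceil(n_features / block_features))
    frames = []
    for b in range(blocks):
        config = SimulationConfig(
            n_ref_samples=n_ref, n_gwas_samples=n_gwas,
            n_variants=block_features * 30,
            chrom_length=block_features * 1_000_000,
            n_features=block_features, cis_h2=0.3, n_causal_per_feature=2,
            ld_rho=0.7, chrom=str(b + 1), seed=seed + 7000 + b,
        )
        panel, truth = simulate_ld_genotypes(config, stream=0)
        gwas, _ = simulate_ld_genotypes(config, n_samples=n_gwas, stream=1,
                                        sample_prefix="gw")
        models, truth2, _ = _train_layer(panel, config, seed=config.seed)
        truth = truth.merge(truth2)
        truth.alpha = {}
        stats = simulate_gwas_summary_stats(gwas, truth, config, mode="logistic")
        db = build_weight_db(models)
        if len(db) == 0:
            continue
        scan = twas_scan(db, stats, panel)
        scan["block"] = b
        frames.append(scan[~scan["skipped"]])
    return pd.concat(frames, ignore_index=True)


def permutation_null_study(
    seed: int = 0, n_features: int = 250, max_perm: int = 1000
) -> pd.DataFrame:
    """Permutation p-values for null features (weights independent of GWAS).

    Entry thresholding is disabled and permutations run to the cap so the
    p-values have enough resolution to check uniformity.
    """
    config = SimulationConfig(
        n_ref_samples=150, n_gwas_samples=2500, n_variants=n_features * 25,
        chrom_length=n_features * 1_000_000, n_features=n_features,
        cis_h2=0.4, n_causal_per_feature=3, ld_rho=0.7, seed=seed + 9000,
    )
    panel, truth = simulate_ld_genotypes(config, stream=0)
    gwas, _ = simulate_ld_genotypes(config, n_samples=config.n_gwas_samples,
                                    stream=1, sample_prefix="gw")
    models, truth2, _ = _train_layer(panel, config, seed=config.seed)
    truth = truth.merge(truth2)
    truth.alpha = {}
    stats = simulate_gwas_summary_stats(gwas, truth, config, mode="logistic")
    rows = []
    for i, model in enumerate(models):
        if model.n_nonzero < 3:
            continue
        cov = snp_covariance(panel, list(model.weights["variant_id"]))
        res = permutation_test(model, stats, cov, max_perm=max_perm,
                               entry_threshold=1.0, early_stop_exceedances=None,
                               seed=seed + 100_000 + i)
        if res.evaluable:
            rows.append({"feature_id": res.feature_id, "perm_p": res.p,
                         "n_perm": res.n_permutations})
    return pd.DataFrame(rows)


def locus_ranking_study(seed: int = 0, n_reps: int = 50) -> pd.DataFrame:
    """Does the truly mediating gene get the locus-best |Z|?

    Per replicate: a 5-feature locus, cis-h2 = 0.3 on a 150-sample panel,
    one feature mediating a case-control GWAS effect.  Success = the causal
    feature is retained and attains the largest |Z| among tested features.
    """
    rows = []
    for rep in range(n_reps):
        config = SimulationConfig(
            n_ref_samples=150, n_gwas_samples=8000, n_variants=250,
            chrom_length=5_000_000, n_features=5, cis_h2=0.3,
            n_causal_per_feature=2, ld_rho=0.8, seed=seed + 3000 + rep,
        )
        panel, truth = simulate_ld_genotypes(config, stream=0)
        gwas, _ = simulate_ld_genotypes(config, n_samples=config.n_gwas_samples,
                                        stream=1, sample_prefix="gw")
        models, truth2, _ = _train_layer(panel, config, seed=config.seed)
        truth = truth.merge(truth2)
        causal_fid = truth.features.index[len(truth.features) // 2]
        truth.alpha = {causal_fid: 0.12}
        stats = simulate_gwas_summary_stats(gwas, truth, config, mode="logistic")
        db = build_weight_db(models)
        if len(db) == 0:
            rows.append({"rep": rep, "success": False, "reason": "no models"})
            continue
        scan = twas_scan(db, stats, panel)
        tested = scan[~scan["skipped"]]
        if causal_fid not in set(tested["feature_id"]):
            rows.append({"rep": rep, "success": False, "reason": "causal not retained"})
            continue
        best = tested.loc[tested["z"].abs().idxmax(), "feature_id"]
        rows.append({"rep": rep, "success": best == causal_fid, "reason": ""})
    return pd.DataFrame(rows)
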