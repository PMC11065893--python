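"""Conditional adjustment algebra and the weight-permutation test."""
import numpy as np
import pandas as pd
import pytest

from twaskit.association import snp_covariance
from twaskit.conditional import (
    conditional_summary_stats,
    conditional_twas,
    find_lead_variant,
    permutation_test,
)
from twaskit.containers import (
    DataError,
    GwasSummaryStats,
    ReferenceCovariance,
    WeightModel,
)

from conftest import make_genotypes


def _stats(rows):
    return GwasSummaryStats(pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "p", "n"]))


def _sim_stats_and_panel(seed=0, n=2000, m=30, rho=0.6):
    """Linear-trait cohort where the panel IS the GWAS sample."""
    from twaskit.synthetic import SimulationConfig, simulate_ld_genotypes, _linear_scan
    cfg = SimulationConfig(n_ref_samples=n, n_gwas_samples=n, n_variants=m,
                           chrom_length=m * 20_000, n_features=1, ld_rho=rho,
                           seed=seed)
    panel, _ = simulate_ld_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    X = panel.mean_imputed()
    y = 0.25 * X[:, 3] - 0.2 * X[:, m // 2] + rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    beta, se, p = _linear_scan(X, y)
    stats = GwasSummaryStats(pd.DataFrame({
        "variant_id": panel.variants["variant_id"],
        "chrom": panel.variants["chrom"], "pos": panel.variants["pos"],
        "effect_allele": panel.variants["alt"],
        "other_allele": panel.variants["ref"],
        "eaf": X.mean(axis=0) / 2.0, "beta": beta, "se": se, "p": p, "n": n,
    }))
    return panel, stats, X, y


class TestConditionalAlgebra:
    def test_uncorrelated_conditioning_leaves_beta_exact(self):
        stats = _stats([
            ["t", "1", 100, "G", "A", 0.3, 0.2, 0.05, 1e-4, 1000],
            ["c", "1", 900000, "G", "A", 0.4, 0.1, 0.05, 0.04, 1000],
        ])
        gamma = np.diag([0.42, 0.48])  # exactly uncorrelated
        cov = ReferenceCovariance(["t", "c"], gamma)
        adj = conditional_summary_stats(stats, ["c"], cov, n=1000)
        assert adj.indexed().loc["t", "beta"] == pytest.approx(0.2, abs=1e-15)

    def test_self_conditioning_zeroes_effect(self):
        stats = _stats([["t", "1", 100, "G", "A", 0.3, 0.2, 0.05, 1e-4, 1000]])
        cov = ReferenceCovariance(["t"], np.array([[0.42]]))
        adj = conditional_summary_stats(stats, ["t"], cov, n=1000)
        row = adj.indexed().loc["t"]
        assert row["beta"] == pytest.approx(0.0, abs=1e-15)
        assert row["p"] == pytest.approx(1.0)

    def test_matches_individual_level_joint_ols(self):
        panel, stats, X, y = _sim_stats_and_panel(seed=3)
        vids = panel.variants["variant_id"].tolist()
        t_id, c_id = vids[3], vids[25]  # causal target, distant conditioner
        cov = snp_covariance(panel, [t_id, c_id])
        adj = conditional_summary_stats(stats, [c_id], cov, n=panel.n_samples)
        b_cond = adj.indexed().loc[t_id, "beta"]
        design = np.column_stack([np.ones(len(y)), X[:, 3], X[:, 25]])
        b_joint = np.linalg.lstsq(design, y, rcond=None)[0][1]
        assert b_cond == pytest.approx(b_joint, rel=0.02)

    def test_multi_variant_conditioning_uses_joint_formula(self):
        # conditioning on two correlated variants at once must match the
        # 2-variant joint solve, not sequential single-variant adjustment
        panel, stats, X, y = _sim_stats_and_panel(seed=4)
        vids = panel.variants["variant_id"].tolist()
        cset = [vids[10], vids[11]]
        cov = snp_covariance(panel, [vids[3]] + cset)
        adj = conditional_summary_stats(stats, cset, cov, n=panel.n_samples)
        b = adj.indexed().loc[vids[3], "beta"]
        # oracle: residual of joint fit, via the same algebra done longhand
        B = panel.n_samples * cov.matrix
        D = np.diag(B)
        beta_marg = stats.indexed().loc[[vids[3]] + cset, "beta"].to_numpy()
        b_c = np.linalg.solve(B[1:, 1:], D[1:] * beta_marg[1:])
        expected = beta_marg[0] - (B[0, 1:] @ b_c) / D[0]
        assert b == pytest.approx(expected, rel=1e-10)

    def test_missing_conditioning_variant_errors(self):
        stats = _stats([["t", "1", 100, "G", "A", 0.3, 0.2, 0.05, 1e-4, 1000]])
        cov = ReferenceCovariance(["t"], np.array([[0.42]]))
        with pytest.raises(DataError):
            conditional_summary_stats(stats, ["absent"], cov, n=1000)

    def test_singular_conditioning_set_errors(self):
        stats = _stats([
            ["a", "1", 100, "G", "A", 0.3, 0.2, 0.05, 1e-4, 1000],
            ["b", "1", 200, "G", "A", 0.3, 0.2, 0.05, 1e-4, 1000],
        ])
        gamma = np.full((2, 2), 0.4)  # perfectly collinear pair
        cov = ReferenceCovariance(["a", "b"], gamma)
        with pytest.raises(DataError, match="prune"):
            conditional_summary_stats(stats, ["a", "b"], cov, n=1000)


class TestLeadVariant:
    ANCHOR = pd.Series({"chrom": "1", "start": 500_000, "end": 500_000})

    def test_nearest_significant_wins_with_p_tiebreak(self):
        stats = _stats([
            ["far", "1", 900_000, "G", "A", 0.3, 0.5, 0.05, 1e-20, 1000],
            ["near", "1", 510_000, "G", "A", 0.3, 0.3, 0.05, 1e-9, 1000],
            ["weak", "1", 505_000, "G", "A", 0.3, 0.1, 0.05, 1e-3, 1000],
            ["tie_a", "1", 490_000, "G", "A", 0.3, 0.3, 0.05, 1e-10, 1000],
        ])
        assert find_lead_variant(self.ANCHOR, stats) == "tie_a"

    def test_no_significant_variant_returns_none(self):
        stats = _stats([["x", "1", 505_000, "G", "A", 0.3, 0.1, 0.05, 1e-3, 1000]])
        assert find_lead_variant(self.ANCHOR, stats) is None

    def test_outside_window_ignored(self):
        stats = _stats([["x", "1", 1_200_000, "G", "A", 0.3, 0.5, 0.05, 1e-20, 1000]])
        assert find_lead_variant(self.ANCHOR, stats) is None


class TestConditionalTwas:
    def test_no_lead_flags_unconditioned_and_keeps_marginal(self):
        panel, stats, _, _ = _sim_stats_and_panel(seed=5, n=400)
        # strip significance so no lead exists
        t = stats.table.copy()
        t["p"] = 0.5
        stats = GwasSummaryStats(t)
        vids = panel.variants["variant_id"].tolist()
        sub = panel.variants.set_index("variant_id").loc[vids[:3]]
        model = WeightModel(
            feature_id="f", layer="expression",
            weights=pd.DataFrame({
                "variant_id": vids[:3], "chrom": "1",
                "pos": sub["pos"].to_numpy(),
                "effect_allele": sub["alt"].to_numpy(),
                "other_allele": sub["ref"].to_numpy(),
                "weight": [0.4, -0.2, 0.1]}),
            cv_r=0.4)
        anchor = pd.Series({"chrom": "1", "start": int(sub["pos"].iloc[0]),
                            "end": int(sub["pos"].iloc[0])})
        res = conditional_twas(model, anchor, stats, panel, n_gwas=400)
        assert not res.conditioned
        assert res.z == res.marginal.z


class TestPermutation:
    def _setup(self, seed=0):
        panel, stats, _, _ = _sim_stats_and_panel(seed=seed, n=500)
        vids = panel.variants["variant_id"].tolist()[:8]
        sub = panel.variants.set_index("variant_id").loc[vids]
        rng = np.random.default_rng(seed)
        model = WeightModel(
            feature_id="f", layer="expression",
            weights=pd.DataFrame({
                "variant_id": vids, "chrom": "1", "pos": sub["pos"].to_numpy(),
                "effect_allele": sub["alt"].to_numpy(),
                "other_allele": sub["ref"].to_numpy(),
                "weight": rng.normal(size=8)}),
            cv_r=0.4)
        cov = snp_covariance(panel, vids)
        return model, stats, cov

    def test_deterministic_given_seed(self):
        model, stats, cov = self._setup()
        a = permutation_test(model, stats, cov, entry_threshold=1.0, seed=7)
        b = permutation_test(model, stats, cov, entry_threshold=1.0, seed=7)
        assert (a.p, a.n_permutations, a.n_exceedances) == \
            (b.p, b.n_permutations, b.n_exceedances)

    def test_exceedance_formula_lower_bound(self):
        # if the observed |Z| beats every permutation, p = 1/(1+N)
        model, stats, cov = self._setup()
        res = permutation_test(model, stats, cov, entry_threshold=1.0,
                               max_perm=200, early_stop_exceedances=None, seed=1)
        assert res.p >= 1.0 / 201.0
        if res.n_exceedances == 0:
            assert res.p == pytest.approx(1.0 / 201.0)
        assert res.p == pytest.approx((1 + res.n_exceedances) / (1 + res.n_permutations))

    def test_too_few_variants_not_evaluable(self):
        model, stats, cov = self._setup()
        small = WeightModel(feature_id="f", layer="expression",
                            weights=model.weights.iloc[:2].reset_index(drop=True),
                            cv_r=0.4)
        res = permutation_test(small, stats, cov, entry_threshold=1.0, seed=2)
        assert not res.evaluable and "fewer than 3" in res.reason

    def test_entry_threshold_skips_weak_signals(self):
        model, stats, cov = self._setup()
        res = permutation_test(model, stats, cov, entry_threshold=1e-30, seed=3)
        assert not res.evaluable and "entry threshold" in res.reason

    def test_early_stopping_caps_work(self):
        model, stats, cov = self._setup(seed=9)
        res = permutation_test(model, stats, cov, entry_threshold=1.0,
                               max_perm=1000, early_stop_exceedances=5,
                               batch=25, seed=4)
        assert res.n_permutations <= 1000
        if res.n_exceedances >= 5:
            assert res.n_permutations < 1000 or res.n_exceedances >= 5
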