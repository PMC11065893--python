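"""The summary-statistic gene-level Z: covariance estimation, the statistic
itself, scan bookkeeping, and replication testing."""
import numpy as np
import pandas as pd
import pytest

from twaskit.association import (
    bonferroni_threshold,
    replication_test,
    snp_covariance,
    twas_scan,
    twas_zscore,
    zscore_from_p,
)
from twaskit.containers import (
    DataError,
    GwasSummaryStats,
    ReferenceCovariance,
    WeightDB,
    WeightModel,
)

from conftest import make_genotypes


def _stats(rows):
    return GwasSummaryStats(pd.DataFrame(rows, columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "p", "n"]))


def _model(weights, ids=None, alleles=None):
    ids = ids or [f"v{i}" for i in range(len(weights))]
    eff = [a[0] for a in alleles] if alleles else ["G"] * len(weights)
    oth = [a[1] for a in alleles] if alleles else ["A"] * len(weights)
    return WeightModel(
        feature_id="feat", layer="expression",
        weights=pd.DataFrame({
            "variant_id": ids, "chrom": "1",
            "pos": range(1000, 1000 + 100 * len(weights), 100),
            "effect_allele": eff, "other_allele": oth, "weight": weights,
        }),
        cv_r=0.5,
    )


class TestSnpCovariance:
    def test_single_variant_sample_variance(self):
        panel = make_genotypes(np.array([[0.0], [1.0], [2.0], [1.0]]))
        cov = snp_covariance(panel, ["v0"])
        assert cov.matrix[0, 0] == pytest.approx(2.0 / 3.0)

    def test_duplicated_column_gives_unit_correlation(self):
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        panel = make_genotypes(np.column_stack([col, col]))
        cov = snp_covariance(panel, ["v0", "v1"])
        assert cov.matrix[0, 1] == pytest.approx(cov.matrix[0, 0])
        w = np.array([1.0, -1.0])
        assert cov.sigma_g(w) == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_dropped_with_warning(self):
        panel = make_genotypes(np.column_stack([[0, 1, 2, 1], [1, 1, 1, 1]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            cov = snp_covariance(panel, ["v0", "v1"])
        assert cov.variant_ids == ["v0"]
        with pytest.raises(DataError):
            snp_covariance(panel, ["v1"])

    def test_symmetric(self, small_panel):
        panel, _ = small_panel
        ids = list(panel.variants["variant_id"][:20])
        cov = snp_covariance(panel, ids)
        assert np.abs(cov.matrix - cov.matrix.T).max() < 1e-12


class TestTwasZscore:
    def test_single_variant_collapses_to_gwas_z(self):
        model = _model([1.0])
        stats = _stats([["v0", "1", 1000, "G", "A", 0.3, 0.12, 0.03, 1e-4, 500]])
        cov = ReferenceCovariance(["v0"], np.array([[0.49]]))
        res = twas_zscore(model, stats, cov)
        assert res.z == pytest.approx(0.12 / 0.03)

    def test_two_perfectly_correlated_variants(self):
        # equal variances, w = (.5, .5), both z: sigma_g = sigma_l, Z = z
        model = _model([0.5, 0.5])
        z_each = 2.0
        stats = _stats([
            ["v0", "1", 1000, "G", "A", 0.3, 0.06, 0.03, 0.05, 500],
            ["v1", "1", 1100, "G", "A", 0.3, 0.06, 0.03, 0.05, 500],
        ])
        var = 0.36
        gamma = np.full((2, 2), var)
        res = twas_zscore(model, stats, ReferenceCovariance(["v0", "v1"], gamma))
        assert res.z == pytest.approx(z_each)

    def test_allele_flip_invariance(self, small_panel, small_config):
        from twaskit.qc import harmonize_alleles
        panel, truth = small_panel
        from twaskit.synthetic import simulate_gwas_summary_stats
        stats = simulate_gwas_summary_stats(panel, truth, small_config)
        ids = list(panel.variants["variant_id"][:5])
        cov = snp_covariance(panel, ids)
        rng = np.random.default_rng(0)
        w = rng.normal(size=5)
        vsub = panel.variants.set_index("variant_id").loc[ids]
        model = WeightModel(
            feature_id="f", layer="expression",
            weights=pd.DataFrame({
                "variant_id": ids, "chrom": "1", "pos": vsub["pos"].to_numpy(),
                "effect_allele": vsub["alt"].to_numpy(),
                "other_allele": vsub["ref"].to_numpy(), "weight": w,
            }), cv_r=0.5)
        base = twas_zscore(model, stats, cov)

        # flip one variant everywhere: swap alleles + negate weight in the
        # model, recode the panel dosage to the other allele (2 - d), and
        # harmonize the GWAS stats to the flipped model
        flipped = model.weights.copy()
        flipped.loc[0, ["effect_allele", "other_allele"]] = (
            flipped.loc[0, ["other_allele", "effect_allele"]].to_numpy())
        flipped.loc[0, "weight"] = -flipped.loc[0, "weight"]
        model_f = WeightModel(feature_id="f", layer="expression",
                              weights=flipped, cv_r=0.5)
        panel_f = make_genotypes(
            np.column_stack([2.0 - panel.dosage_for([ids[0]])[:, 0],
                             panel.dosage_for(ids[1:])]))
        cov_f = snp_covariance(panel_f, [f"v{i}" for i in range(5)])
        cov_f = ReferenceCovariance(ids, cov_f.matrix)
        harm, _ = harmonize_alleles(
            flipped[["variant_id", "effect_allele", "other_allele"]], stats)
        res = twas_zscore(model_f, harm, cov_f)
        assert res.z == pytest.approx(base.z, abs=1e-12)

    def test_weight_scale_invariance(self):
        model_a = _model([0.2, -0.4, 0.1])
        model_b = _model([1.0, -2.0, 0.5])
        rows = [[f"v{i}", "1", 1000 + i, "G", "A", 0.3, 0.05 * (i + 1), 0.03,
                 0.05, 500] for i in range(3)]
        stats = _stats(rows)
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        gamma = np.cov(a, rowvar=False)
        cov = ReferenceCovariance(["v0", "v1", "v2"], gamma)
        za = twas_zscore(model_a, stats, cov).z
        zb = twas_zscore(model_b, stats, cov).z
        assert abs(za) == pytest.approx(abs(zb))

    def test_missing_gwas_variants_dropped_and_counted(self):
        model = _model([0.5, 0.5, 1.5])
        stats = _stats([["v0", "1", 1000, "G", "A", 0.3, 0.06, 0.03, 0.05, 500]])
        gamma = np.eye(3) * 0.4
        cov = ReferenceCovariance(["v0", "v1", "v2"], gamma)
        with pytest.warns(UserWarning, match="weight mass"):
            res = twas_zscore(model, stats, cov)
        assert res.n_used == 1 and res.n_dropped == 2
        assert res.weight_mass_dropped == pytest.approx(0.8)

    def test_empty_intersection_skipped(self):
        model = _model([1.0])
        stats = _stats([["other", "1", 9, "G", "A", 0.3, 0.06, 0.03, 0.05, 500]])
        cov = ReferenceCovariance(["v0"], np.array([[0.4]]))
        res = twas_zscore(model, stats, cov)
        assert res.skipped and "no model variants" in res.skip_reason


class TestScanAndReplication:
    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(9982) == 0.05 / 9982
        with pytest.raises(DataError):
            bonferroni_threshold(0)

    def test_scan_per_layer_m_and_significance(self, small_panel, small_config):
        panel, truth = small_panel
        from twaskit.synthetic import simulate_gwas_summary_stats
        stats = simulate_gwas_summary_stats(panel, truth, small_config)
        db = WeightDB()
        vsub = panel.variants
        for i, fid in enumerate(["fa", "fb"]):
            ids = list(vsub["variant_id"][5 * i: 5 * i + 3])
            sub = vsub.set_index("variant_id").loc[ids]
            db.add(WeightModel(
                feature_id=fid, layer="expression",
                weights=pd.DataFrame({
                    "variant_id": ids, "chrom": "1", "pos": sub["pos"].to_numpy(),
                    "effect_allele": sub["alt"].to_numpy(),
                    "other_allele": sub["ref"].to_numpy(),
                    "weight": [0.2, -0.1, 0.4],
                }), cv_r=0.3))
        out = twas_scan(db, stats, panel)
        assert len(out) == 2
        assert (out["m"] == 2).all()
        assert (out["threshold"] == 0.05 / 2).all()
        assert ((out["p"] < out["threshold"]) == out["significant"]).all()

    def test_replication_directions(self):
        assert replication_test(2.4, 1) == pytest.approx(8.2e-3, rel=0.01)
        assert replication_test(-2.4, 1) == pytest.approx(0.9918, rel=1e-3)
        assert replication_test(0.0, 1) == 0.5
        assert replication_test(-2.4, -1) < 0.05
        with pytest.raises(DataError):
            replication_test(1.0, 0)

    def test_zscore_from_p_round_trips(self):
        from scipy import stats as sps
        for z in (0.5, 2.4, 4.7):
            p2 = 2 * sps.norm.sf(z)
            assert zscore_from_p(p2) == pytest.approx(z, rel=1e-10)
            p1 = sps.norm.sf(z)
            assert zscore_from_p(p1, one_sided=True) == pytest.approx(z, rel=1e-10)
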