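"""Variant-level QC and allele harmonization.

Default thresholds reproduce a standard imputed-array cleaning recipe for
prediction-model building: drop variants with minor allele frequency < 5%,
Hardy-Weinberg exact-test p < 1e-4, missing genotyping rate > 5%, or
imputation quality r^2 < 0.8 (when available), plus multi-allelic and
strand-ambiguous (A/T, C/G) variants.  All printed inequalities are strict:
a variant sitting exactly on a threshold passes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DataError, GenotypeMatrix, GwasSummaryStats

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class QcThresholds:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-4
    missing_max: float = 0.05
    imputation_r2_min: float = 0.8
    drop_multiallelic: bool = True
    drop_ambiguous: bool = True
    hwe_method: str = "exact"  # or "chisq"


@dataclass
class QcReport:
    """Per-variant QC outcome with failure reasons and tallies."""

    table: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    def to_tsv(self, path) -> None:
        failed = self.table[~self.table["retained"]]
        failed.to_csv(path, sep="\t", index=False)


def allele_stats(dosages: np.ndarray) -> dict:
    """Alt-allele frequency, MAF, missing rate and hard-call counts.

    Genotype counts (hom-ref, het, hom-alt) are derived from hard calls;
    dosages further than 0.1 from an integer are left out of the counts
    (they still contribute to frequency and missingness).
    """
    d = np.asarray(dosages, dtype=float)
    missing = np.isnan(d)
    n_obs = int((~missing).sum())
    if n_obs == 0:
        raise DataError("all genotypes missing")
    obs = d[~missing]
    alt_freq = float(obs.sum() / (2 * n_obs))
    hard = np.rint(obs)
    callable_ = np.abs(obs - hard) <= 0.1
    hc = hard[callable_].astype(int)
    counts = (int((hc == 0).sum()), int((hc == 1).sum()), int((hc == 2).sum()))
    return {
        "alt_freq": alt_freq,
        "maf": min(alt_freq, 1.0 - alt_freq),
        "missing_rate": float(missing.mean()),
        "genotype_counts": counts,
    }


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test by enumeration over heterozygote counts.

    Sums the probabilities of all genotype tables (with the observed allele
    counts) whose probability does not exceed that of the observed table.
    Monomorphic variants return p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise DataError("empty genotype counts")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log-probability of each possible het count with the same allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1) - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chisq_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square HWE test (asymptotic alternative)."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise DataError("empty genotype counts")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    from scipy.stats import chi2

    return float(chi2.sf(stat, df=1))


def hwe_test(genotype_counts: tuple[int, int, int], method: str = "exact") -> float:
    n_aa, n_ab, n_bb = genotype_counts
    if method == "exact":
        return hwe_exact_test(n_aa, n_ab, n_bb)
    if method == "chisq":
        return hwe_chisq_test(n_aa, n_ab, n_bb)
    raise DataError(f"unknown HWE method {method!r}")


def is_ambiguous(ref: str, alt: str) -> bool:
    return frozenset((ref, alt)) in AMBIGUOUS_PAIRS


def qc_filter(
    panel: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply variant-level QC to a genotype panel.

    Returns the filtered panel and a report listing, per variant, which
    filters it failed.  Applying the filter twice gives the same panel.
    """
    if panel.n_variants == 0:
        raise DataError("empty genotype panel")
    thr = thresholds or QcThresholds()
    rows = []
    for j in range(panel.n_variants):
        v = panel.variants.iloc[j]
        reasons = []
        try:
            st = allele_stats(panel.dosages[:, j])
        except DataError:
            st = {"alt_freq": np.nan, "maf": np.nan, "missing_rate": 1.0,
                  "genotype_counts": (0, 0, 0)}
            reasons.append("missing")
        if st["maf"] < thr.maf_min and "missing" not in reasons:
            reasons.append("maf")
        if st["missing_rate"] > thr.missing_max and "missing" not in reasons:
            reasons.append("missing")
        if sum(st["genotype_counts"]) > 0:
            hwe_p = hwe_test(st["genotype_counts"], thr.hwe_method)
            if hwe_p < thr.hwe_p_min:
                reasons.append("hwe")
        else:
            hwe_p = np.nan
        r2 = v["imputation_r2"]
        if pd.notna(r2) and r2 < thr.imputation_r2_min:
            reasons.append("imputation")
        if thr.drop_multiallelic and bool(v["multiallelic"]):
            reasons.append("multiallelic")
        if thr.drop_ambiguous and is_ambiguous(v["ref"], v["alt"]):
            reasons.append("ambiguous")
        rows.append(
            {
                "variant_id": v["variant_id"], "chrom": v["chrom"], "pos": v["pos"],
                "maf": st["maf"], "missing_rate": st["missing_rate"],
                "hwe_p": hwe_p, "imputation_r2": r2,
                "retained": not reasons, "reasons": ",".join(reasons),
            }
        )
    report_table = pd.DataFrame(rows)
    counts: dict[str, int] = {}
    for rs in report_table.loc[~report_table["retained"], "reasons"]:
        for reason in rs.split(","):
            counts[reason] = counts.get(reason, 0) + 1
    counts["retained"] = int(report_table["retained"].sum())
    counts["excluded"] = int((~report_table["retained"]).sum())
    keep = report_table["retained"].to_numpy()
    if not keep.any():
        warnings.warn("QC removed every variant")
    filtered = panel.subset_variants(keep)
    return filtered, QcReport(table=report_table, counts=counts)


def harmonize_alleles(
    model_variants: pd.DataFrame, stats: GwasSummaryStats
) -> tuple[GwasSummaryStats, pd.DataFrame]:
    """Align GWAS summary statistics to the weight models' effect alleles.

    Matching alleles pass through unchanged; swapped alleles get beta
    negated and EAF complemented; mismatched or strand-ambiguous pairs are
    dropped and reported.  Variants absent from the model list pass through
    untouched (they are simply never used downstream).
    """
    for side, df in (("model", model_variants), ("GWAS", stats.table)):
        if df["variant_id"].duplicated().any():
            raise DataError(f"duplicate variant ids on the {side} side")
    model = model_variants.set_index("variant_id")
    table = stats.table.copy()
    drops = []
    keep_mask = np.ones(len(table), dtype=bool)
    for i, row in table.iterrows():
        vid = row["variant_id"]
        if vid not in model.index:
            continue
        m_eff = model.loc[vid, "effect_allele"]
        m_oth = model.loc[vid, "other_allele"]
        g_eff, g_oth = row["effect_allele"], row["other_allele"]
        if is_ambiguous(g_eff, g_oth):
            drops.append({"variant_id": vid, "reason": "ambiguous"})
            keep_mask[i] = False
        elif (g_eff, g_oth) == (m_eff, m_oth):
            continue
        elif (g_eff, g_oth) == (m_oth, m_eff):
            table.loc[i, "beta"] = -row["beta"]
            table.loc[i, "eaf"] = 1.0 - row["eaf"]
            table.loc[i, "effect_allele"] = m_eff
            table.loc[i, "other_allele"] = m_oth
        else:
            drops.append({"variant_id": vid, "reason": "allele_mismatch"})
            keep_mask[i] = False
    harmonized = GwasSummaryStats(table[keep_mask].reset_index(drop=True))
    drop_report = pd.DataFrame(drops, columns=["variant_id", "reason"])
    return harmonized, drop_report
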