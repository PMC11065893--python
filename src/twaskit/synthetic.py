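"""Synthetic reference-panel / GWAS cohort generator with known ground truth.

Emulates the data-generating assumptions behind a multi-layer TWAS study:

* LD-structured diploid genotypes.  Each haplotype is a Gaussian-copula
  AR(1) latent chain over variants, thresholded at the allele frequency, so
  adjacent-variant correlation is tunable via ``ld_rho`` and genotypes
  satisfy Hardy-Weinberg proportions at the drawn frequency.
* Cis-regulated molecular phenotypes for three layers: expression
  (TPM-like positive values), 3'UTR alternative polyadenylation (PDUI from
  simulated proximal/distal read counts) and exon-junction splicing (PSI
  from inclusion/exclusion counts).  Each feature has a small set of causal
  cis variants whose combined latent effect explains ``cis_h2`` of latent
  variance, plus covariate/batch structure and Gaussian noise.
* Case-control GWAS summary statistics whose risk signal is mediated by
  chosen causal features: liability is a weighted sum of the features'
  genetic values; case status is assigned by liability threshold; marginal
  per-variant effects come from vectorised logistic regression (or linear
  regression on the continuous liability, for exact oracle comparisons).

Everything is driven by a single integer seed; identical configs produce
bit-identical outputs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri
from scipy import stats as sps

from .containers import (
    ConfigurationError,
    CovariateMatrix,
    DataError,
    GenotypeMatrix,
    GwasSummaryStats,
    MolecularPhenotypeMatrix,
    SUMSTAT_COLUMNS,
)

_LAYER_PREFIX = {"expression": "gene", "apa": "apa", "junction": "junc"}
_LAYER_STREAM = {"expression": 0, "apa": 1, "junction": 2}
# non strand-ambiguous allele pairs only; QC-fixture generators add A/T etc.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Fractions are validated on construction; the same config (including
    ``seed``) always yields bit-identical data.
    """

    n_ref_samples: int = 150
    n_gwas_samples: int = 5000
    n_variants: int = 300
    chrom_length: int = 10_000_000
    chrom: str = "1"
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.7
    n_features: int = 10
    cis_window: int = 500_000
    cis_h2: float = 0.3
    n_causal_per_feature: int = 3
    n_causal_features: int = 0
    feature_effect_var: float = 0.005
    case_fraction: float = 0.45
    missing_rate: float = 0.0
    covariate_var: float = 0.1
    mean_log2_tpm: float = 5.0
    read_depth: float = 50.0
    min_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ConfigurationError("n_variants must be positive")
        if self.n_ref_samples <= 0 or self.n_gwas_samples <= 0:
            raise ConfigurationError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if not (0 <= self.cis_h2 < 1):
            raise ConfigurationError("cis_h2 must lie in [0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not (0 <= self.covariate_var < 1 - self.cis_h2):
            raise ConfigurationError("covariate_var must lie in [0, 1 - cis_h2)")
        if self.feature_effect_var < 0:
            raise ConfigurationError("feature_effect_var must be >= 0")
        if self.n_causal_per_feature < 0 or self.n_features <= 0:
            raise ConfigurationError("feature counts must be positive")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the simulated data."""

    variant_eaf: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    causal_variants: dict[str, pd.DataFrame] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None

    def merge(self, other: "SimulationTruth") -> "SimulationTruth":
        feats = pd.concat([self.features, other.features]) if len(self.features) else other.features
        eaf = other.variant_eaf if len(other.variant_eaf) else self.variant_eaf
        return SimulationTruth(
            variant_eaf=eaf,
            features=feats,
            causal_variants={**self.causal_variants, **other.causal_variants},
            alpha={**self.alpha, **other.alpha},
            covariates=self.covariates if other.covariates is None else other.covariates,
        )


def _variant_frame(config: SimulationConfig) -> pd.DataFrame:
    """Variant metadata shared by every cohort drawn from one config."""
    rng = np.random.default_rng([config.seed, 101])
    m = config.n_variants
    spacing = config.chrom_length / m
    pos = (np.arange(m) * spacing + rng.uniform(0, spacing, m)).astype(np.int64) + 1
    for j in range(1, m):  # enforce strictly increasing 1-based positions
        if pos[j] <= pos[j - 1]:
            pos[j] = pos[j - 1] + 1
    freq = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    ref = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    alt = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return pd.DataFrame(
        {
            "variant_id": [f"chr{config.chrom}_{p}" for p in pos],
            "chrom": config.chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "imputation_r2": 1.0,
            "multiallelic": False,
            "true_alt_freq": freq,
        }
    )


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n, m))
    if rho > 0 and m > 1:
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + c * z[:, j]
    return z


def simulate_ld_genotypes(
    config: SimulationConfig,
    n_samples: int | None = None,
    stream: int = 0,
    sample_prefix: str = "ref",
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw an LD-structured diploid genotype matrix.

    ``stream`` separates cohorts (reference panel vs GWAS) that share the
    same variant metadata and true allele frequencies but independent
    samples.  Hard-call dosages in {0, 1, 2}; missingness injected uniformly
    at ``config.missing_rate``.
    """
    vf = _variant_frame(config)
    n = config.n_ref_samples if n_samples is None else n_samples
    rng = np.random.default_rng([config.seed, 202, stream])
    thresh = ndtri(vf["true_alt_freq"].to_numpy())
    geno = np.zeros((n, len(vf)))
    for _hap in range(2):
        z = _ar1_latent(rng, n, len(vf), config.ld_rho)
        geno += (z < thresh[None, :]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = np.nan
    samples = [f"{sample_prefix}{i:05d}" for i in range(n)]
    truth = SimulationTruth(
        variant_eaf=pd.Series(vf["true_alt_freq"].to_numpy(), index=vf["variant_id"]),
    )
    gm = GenotypeMatrix(samples=samples, dosages=geno,
                        variants=vf.drop(columns=["true_alt_freq"]))
    return gm, truth


def _feature_anchors(config: SimulationConfig, layer: str) -> pd.DataFrame:
    prefix = _LAYER_PREFIX[layer]
    spacing = config.chrom_length / config.n_features
    mids = ((np.arange(config.n_features) + 0.5) * spacing).astype(np.int64)
    ids = [f"{prefix}{i:04d}" for i in range(config.n_features)]
    return pd.DataFrame(
        {"chrom": config.chrom, "start": mids, "end": mids, "strand": "+"},
        index=pd.Index(ids, name="feature_id"),
    )


def simulate_molecular_phenotypes(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    layer: str = "expression",
) -> tuple[MolecularPhenotypeMatrix, SimulationTruth]:
    """Simulate a cis-regulated molecular phenotype layer on ``geno``'s samples.

    Each feature's latent value is genetic + covariate + noise with unit
    total variance and genetic fraction ``cis_h2``.  The latent value is
    mapped to the layer's observation scale (TPM via 2**latent; PDUI / PSI
    via a logit-linear count model with depth-based missingness).
    """
    if layer not in _LAYER_PREFIX:
        raise ConfigurationError(f"unknown layer {layer!r}")
    rng = np.random.default_rng([config.seed, 303, _LAYER_STREAM[layer]])
    anchors = _feature_anchors(config, layer)
    n = geno.n_samples
    X = geno.mean_imputed()
    pos = geno.variants["pos"].to_numpy()
    vids = geno.variants["variant_id"].to_numpy()

    # shared covariate/batch structure: standardized age + a binary batch
    age = rng.standard_normal(n)
    batch = (rng.random(n) < 0.5).astype(float)
    cov = np.column_stack([age, batch - batch.mean()])
    cov_table = pd.DataFrame(cov, index=geno.samples, columns=["age", "batch"])

    values = np.empty((len(anchors), n))
    keep_rows: list[int] = []
    causal: dict[str, pd.DataFrame] = {}
    realized = []
    for i, (fid, row) in enumerate(anchors.iterrows()):
        lo = max(1, row["start"] - config.cis_window)
        hi = row["end"] + config.cis_window
        cis_idx = np.flatnonzero((pos >= lo) & (pos <= hi))
        if cis_idx.size == 0:
            warnings.warn(f"feature {fid}: empty cis window, skipped")
            continue
        n_causal = min(config.n_causal_per_feature, cis_idx.size)
        pick = rng.choice(cis_idx, size=n_causal, replace=False)
        pick.sort()
        beta = rng.standard_normal(n_causal)
        g = X[:, pick] @ beta
        sd_g = g.std()
        if config.cis_h2 > 0 and sd_g > 0:
            beta = beta * np.sqrt(config.cis_h2) / sd_g
            g = g * np.sqrt(config.cis_h2) / sd_g
        else:
            beta = np.zeros(n_causal)
            g = np.zeros(n)
        gamma = rng.standard_normal(cov.shape[1])
        c = cov @ gamma
        if c.std() > 0 and config.covariate_var > 0:
            c = c * np.sqrt(config.covariate_var) / c.std()
        else:
            c = np.zeros(n)
        resid_sd = np.sqrt(max(1.0 - config.cis_h2 - config.covariate_var, 0.0))
        y = g + c + rng.standard_normal(n) * resid_sd
        var_y = y.var()
        realized.append(g.var() / var_y if var_y > 0 else 0.0)
        causal[fid] = pd.DataFrame({"variant_id": vids[pick], "beta": beta})
        values[len(keep_rows)] = y
        keep_rows.append(i)

    anchors = anchors.iloc[keep_rows]
    latent = values[: len(keep_rows)]

    if layer == "expression":
        obs = np.power(2.0, latent + config.mean_log2_tpm)
    else:
        base = logit(rng.uniform(0.25, 0.75, size=len(anchors)))
        prob = expit(base[:, None] + latent)
        totals = rng.poisson(config.read_depth, size=prob.shape)
        hits = rng.binomial(totals, prob)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
        obs[totals < config.min_depth] = np.nan

    pheno = MolecularPhenotypeMatrix(
        layer=layer,
        values=pd.DataFrame(obs, index=anchors.index, columns=geno.samples),
        anchors=anchors,
    )
    features = anchors.copy()
    features["layer"] = layer
    features["realized_h2"] = realized
    truth = SimulationTruth(features=features, causal_variants=causal,
                            covariates=cov_table)
    return pheno, truth


def genetic_values(
    geno: GenotypeMatrix,
    truth: SimulationTruth,
    feature_ids: list[str] | None = None,
) -> pd.DataFrame:
    """True genetic value of each feature evaluated on ``geno``'s samples."""
    ids = feature_ids if feature_ids is not None else list(truth.causal_variants)
    X = geno.mean_imputed()
    out = {}
    for fid in ids:
        cv = truth.causal_variants[fid]
        out[fid] = X[:, geno.index_of(cv["variant_id"])] @ cv["beta"].to_numpy()
    return pd.DataFrame(out, index=geno.samples)


def choose_causal_features(
    truth: SimulationTruth,
    config: SimulationConfig,
    layer: str = "expression",
) -> dict[str, float]:
    """Select ``n_causal_features`` features and assign liability effects.

    Each chosen feature gets |alpha| = sqrt(feature_effect_var) with random
    sign; the mapping is stored on ``truth.alpha`` and returned.
    """
    rng = np.random.default_rng([config.seed, 404])
    fids = [f for f in truth.features.index if truth.features.loc[f, "layer"] == layer]
    k = min(config.n_causal_features, len(fids))
    chosen = rng.choice(np.array(fids, dtype=object), size=k, replace=False)
    amp = np.sqrt(config.feature_effect_var)
    signs = rng.choice([-1.0, 1.0], size=k)
    truth.alpha.update({fid: float(s * amp) for fid, s in zip(chosen, signs)})
    return truth.alpha


def _linear_scan(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    beta = xc.T @ yc / sxx
    sse = (yc @ yc) - beta * beta * sxx
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    p = 2.0 * sps.t.sf(np.abs(beta / se), df=n - 2)
    return beta, se, p


def _logistic_scan(
    x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant univariate logistic regression (intercept + dosage), IRLS."""
    m = x.shape[1]
    b0 = np.full(m, logit(y.mean()))
    b1 = np.zeros(m)
    ycol = y[:, None]
    s00 = s01 = s11 = det = None
    for _ in range(max_iter):
        eta = b0[None, :] + x * b1[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = ycol - mu
        g0 = r.sum(axis=0)
        g1 = (r * x).sum(axis=0)
        s00 = w.sum(axis=0)
        wx = w * x
        s01 = wx.sum(axis=0)
        s11 = (wx * x).sum(axis=0)
        det = s00 * s11 - s01 * s01
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(), np.abs(d1).max()) < tol:
            break
    se = np.sqrt(s00 / det)
    p = 2.0 * sps.norm.sf(np.abs(b1 / se))
    return b1, se, p


def simulate_gwas_summary_stats(
    geno_gwas: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    mode: str = "logistic",
    alphas: dict[str, float] | None = None,
) -> GwasSummaryStats:
    """Per-variant marginal association statistics for the GWAS cohort.

    Liability is the alpha-weighted sum of (cohort-standardised) feature
    genetic values plus Gaussian noise with total unit variance.  In
    ``logistic`` mode, cases are the top ``case_fraction`` of liability and
    effects are per-allele log-odds ratios; in ``linear`` mode the
    continuous liability itself is regressed on each dosage.
    """
    if mode not in ("logistic", "linear"):
        raise ConfigurationError(f"unknown GWAS mode {mode!r}")
    alphas = dict(truth.alpha if alphas is None else alphas)
    var_gen = sum(a * a for a in alphas.values())
    if var_gen >= 1.0:
        raise ConfigurationError("sum of squared feature effects must be < 1")
    rng = np.random.default_rng([config.seed, 505])
    n = geno_gwas.n_samples
    liability = np.zeros(n)
    if alphas:
        gvals = genetic_values(geno_gwas, truth, list(alphas))
        for fid, a in alphas.items():
            g = gvals[fid].to_numpy()
            sd = g.std()
            if sd > 0:
                liability += a * (g - g.mean()) / sd
    liability += rng.standard_normal(n) * np.sqrt(1.0 - var_gen)

    X = geno_gwas.mean_imputed()
    eaf = X.mean(axis=0) / 2.0
    ok = (eaf > 0) & (eaf < 1)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} monomorphic variants dropped from summary stats")
    Xok = X[:, ok]

    if mode == "linear":
        y = liability
        beta, se, p = _linear_scan(Xok, y)
    else:
        thr = np.quantile(liability, 1.0 - config.case_fraction)
        y = (liability >= thr).astype(float)
        if y.min() == y.max():
            raise DataError("degenerate phenotype: all cases or all controls")
        beta = np.empty(Xok.shape[1])
        se = np.empty_like(beta)
        p = np.empty_like(beta)
        for start in range(0, Xok.shape[1], 512):  # bound peak memory
            sl = slice(start, min(start + 512, Xok.shape[1]))
            beta[sl], se[sl], p[sl] = _logistic_scan(Xok[:, sl], y)

    vf = geno_gwas.variants.loc[ok].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "variant_id": vf["variant_id"],
            "chrom": vf["chrom"],
            "pos": vf["pos"],
            "effect_allele": vf["alt"],
            "other_allele": vf["ref"],
            "eaf": eaf[ok],
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        },
        columns=SUMSTAT_COLUMNS,
    )
    return GwasSummaryStats(table)


@dataclass
class SimulatedStudy:
    """A complete simulated study: panel, phenotypes, GWAS stats, truth."""

    config: SimulationConfig
    ref_genotypes: GenotypeMatrix
    gwas_genotypes: GenotypeMatrix
    phenotypes: dict[str, MolecularPhenotypeMatrix]
    covariates: CovariateMatrix
    gwas_stats: GwasSummaryStats
    truth: SimulationTruth


def simulate_study(
    config: SimulationConfig,
    layers: tuple[str, ...] = ("expression",),
    gwas_mode: str = "logistic",
    alphas: dict[str, float] | None = None,
) -> SimulatedStudy:
    """Run the whole generator: panel + phenotypes + GWAS summary stats."""
    ref, truth = simulate_ld_genotypes(config, stream=0, sample_prefix="ref")
    gwas, _ = simulate_ld_genotypes(
        config, n_samples=config.n_gwas_samples, stream=1, sample_prefix="gw"
    )
    phenos: dict[str, MolecularPhenotypeMatrix] = {}
    for layer in layers:
        pheno, ptruth = simulate_molecular_phenotypes(ref, config, layer)
        phenos[layer] = pheno
        truth = truth.merge(ptruth)
    if alphas is None and config.n_causal_features > 0:
        choose_causal_features(truth, config, layer=layers[0])
    elif alphas is not None:
        truth.alpha.update(alphas)
    stats = simulate_gwas_summary_stats(gwas, truth, config, mode=gwas_mode)
    covariates = CovariateMatrix(truth.covariates if truth.covariates is not None
                                 else pd.DataFrame(index=ref.samples))
    return SimulatedStudy(
        config=config,
        ref_genotypes=ref,
        gwas_genotypes=gwas,
        phenotypes=phenos,
        covariates=covariates,
        gwas_stats=stats,
        truth=truth,
    )
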