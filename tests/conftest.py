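import numpy as np
import pandas as pd
import pytest

from twaskit.containers import GenotypeMatrix
from twaskit.synthetic import SimulationConfig, simulate_ld_genotypes


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_ref_samples=120, n_gwas_samples=600, n_variants=150,
        chrom_length=5_000_000, n_features=5, cis_h2=0.4,
        n_causal_per_feature=2, ld_rho=0.7, seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = simulate_ld_genotypes(small_config)
    return panel, truth


def make_genotypes(dosages, pos=None, ref=None, alt=None, r2=None, multi=None,
                   chrom="1"):
    """Hand-build a GenotypeMatrix from a samples x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pos = list(range(1000, 1000 + 100 * m, 100)) if pos is None else pos
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref if ref is not None else ["A"] * m,
            "alt": alt if alt is not None else ["G"] * m,
            "imputation_r2": r2 if r2 is not None else [np.nan] * m,
            "multiallelic": multi if multi is not None else [False] * m,
        }
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)], dosages=dosages,
                          variants=variants)
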