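import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate import HarmonizedTable, SumStatTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_harmonized(gamma, Gamma, se_Gamma, se_gamma=None, snps=None) -> HarmonizedTable:
    """Assemble a HarmonizedTable directly from effect arrays."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    se_Gamma = np.asarray(se_Gamma, dtype=float)
    se_gamma = np.full_like(gamma, 0.01) if se_gamma is None else np.asarray(se_gamma, dtype=float)
    snps = [f"rs{i + 1}" for i in range(len(gamma))] if snps is None else list(snps)
    return HarmonizedTable(
        pd.DataFrame(
            {
                "snp": snps,
                "gamma": gamma,
                "se_gamma": se_gamma,
                "Gamma": Gamma,
                "se_Gamma": se_Gamma,
                "eaf_exposure": 0.3,
                "eaf_outcome": 0.3,
                "action": "unchanged",
            }
        )
    )


def build_sumstats(
    snps,
    betas,
    ses,
    pvals=None,
    eafs=None,
    n=10_000,
    effect_alleles=None,
    other_alleles=None,
    label="trait",
    trait_type="quantitative",
) -> SumStatTable:
    k = len(snps)
    from scipy import stats

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if pvals is None:
        pvals = 2 * stats.norm.sf(np.abs(betas) / ses)
    df = pd.DataFrame(
        {
            "snp": list(snps),
            "effect_allele": effect_alleles if effect_alleles is not None else ["A"] * k,
            "other_allele": other_alleles if other_alleles is not None else ["G"] * k,
            "eaf": eafs if eafs is not None else [0.3] * k,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n": n,
        }
    )
    return SumStatTable(df, trait_label=label, trait_type=trait_type)


@pytest.fixture
def make_h():
    return build_harmonized


@pytest.fixture
def make_table():
    return build_sumstats
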