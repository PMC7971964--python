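import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sleepmet import HarmonizedSet, SummaryDataset, TraitKind

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_summary_table(rng: np.random.Generator, n: int, *, palindromic_ok=True) -> pd.DataFrame:
    """A random valid canonical summary-statistics table."""
    pairs = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
    if not palindromic_ok:
        pairs = [p for p in pairs if set(p) not in ({"A", "T"}, {"C", "G"})]
    pick = rng.integers(0, len(pairs), size=n)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": [str(1 + i % 22) for i in range(n)],
            "pos": 1000 + 500 * np.arange(n),
            "effect_allele": [pairs[k][0] for k in pick],
            "other_allele": [pairs[k][1] for k in pick],
            "eaf": rng.uniform(0.05, 0.95, size=n),
            "beta": rng.normal(0, 0.1, size=n),
            "se": rng.uniform(0.005, 0.05, size=n),
            "pval": rng.uniform(1e-12, 1.0, size=n),
            "n": rng.integers(1000, 50_000, size=n),
        }
    )


def make_harmonized(
    rng: np.random.Generator, n: int, *, exposure="insomnia", outcome="met_001"
) -> HarmonizedSet:
    """A random harmonized set with positive SEs and nonzero beta_exp."""
    bx = rng.normal(0, 0.1, size=n)
    bx[bx == 0] = 0.01
    return HarmonizedSet(
        exposure_name=exposure,
        outcome_name=outcome,
        table=pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n)],
                "effect_allele": ["A"] * n,
                "other_allele": ["G"] * n,
                "beta_exp": bx,
                "se_exp": rng.uniform(0.005, 0.03, size=n),
                "beta_out": rng.normal(0, 0.05, size=n),
                "se_out": rng.uniform(0.005, 0.05, size=n),
                "eaf_exp": rng.uniform(0.1, 0.9, size=n),
                "eaf_out": rng.uniform(0.1, 0.9, size=n),
            }
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def summary_dataset(rng) -> SummaryDataset:
    return SummaryDataset(
        trait_name="insomnia",
        trait_kind=TraitKind.BINARY_EXPOSURE,
        table=make_summary_table(rng, 20),
    )
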