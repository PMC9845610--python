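import numpy as np
import pandas as pd
import pytest


def make_instruments(beta_exp, beta_out, se_out, se_exp=None, rsids=None):
    """Build a minimal harmonized-instrument frame for the estimators."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    j = len(beta_exp)
    if se_exp is None:
        se_exp = np.full(j, 1e-6)
    if rsids is None:
        rsids = [f"rs{i + 1}" for i in range(j)]
    return pd.DataFrame(
        {
            "rsid": rsids,
            "beta_exp": beta_exp,
            "se_exp": np.asarray(se_exp, dtype=float),
            "beta_out": beta_out,
            "se_out": se_out,
        }
    )


@pytest.fixture
def two_instruments():
    """The hand-worked pair: equal weights 400, ratios 0.10 and 0.20."""
    return make_instruments(
        beta_exp=[0.10, 0.20], beta_out=[0.010, 0.040], se_out=[0.005, 0.010]
    )


@pytest.fixture
def sumstats_frame():
    """Five valid variants on separate chromosomes."""
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(1, 6)],
            "chrom": ["1", "2", "3", "4", "5"],
            "pos": [1000, 2000, 3000, 4000, 5000],
            "effect_allele": ["A", "C", "G", "T", "A"],
            "other_allele": ["G", "T", "A", "C", "C"],
            "eaf": [0.2, 0.3, 0.4, 0.25, 0.35],
            "beta": [0.10, 0.12, -0.08, 0.15, 0.09],
            "se": [0.01, 0.012, 0.011, 0.013, 0.01],
            "pval": [1e-20, 1e-22, 1e-12, 1e-28, 1e-18],
            "n": [50_000] * 5,
        }
    )
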