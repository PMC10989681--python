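import numpy as np
import pandas as pd
import pytest


def make_stats(rows: list[dict]) -> pd.DataFrame:
    """Canonical summary-statistics frame from terse row dicts."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.02,
        "pval": 1e-8,
        "n": 5000,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"snp_id": f"rs{i + 1}", **defaults, **row}
        out.append(rec)
    df = pd.DataFrame(out)
    return df[
        ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
         "eaf", "beta", "se", "pval", "n"]
    ]


def make_harmonized(
    gamma, big_gamma, exposure_se=0.01, outcome_se=0.02, action="kept"
) -> pd.DataFrame:
    """Hand-built harmonized-instrument frame for estimator tests."""
    gamma = np.asarray(gamma, dtype=float)
    big_gamma = np.asarray(big_gamma, dtype=float)
    j = len(gamma)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(j)],
            "chrom": "1",
            "pos": np.arange(j) * 10**8 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "exposure_beta": gamma,
            "exposure_se": np.broadcast_to(exposure_se, j).astype(float),
            "exposure_eaf": 0.3,
            "exposure_pval": 1e-8,
            "exposure_n": 5000,
            "outcome_beta": big_gamma,
            "outcome_se": np.broadcast_to(outcome_se, j).astype(float),
            "outcome_eaf": 0.3,
            "palindromic": False,
            "action": action,
            "reason": "alleles_match",
        }
    )


@pytest.fixture
def stats_file(tmp_path):
    """Write a canonical frame to a TSV and return the path."""

    def _write(df: pd.DataFrame, name: str = "stats.tsv", sep: str = "\t"):
        path = tmp_path / name
        df.to_csv(path, sep=sep, index=False)
        return path

    return _write
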