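import numpy as np
import pandas as pd
import pytest

from epitriage.io import BetaMatrix
from epitriage.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    return generate_cohort(CohortConfig(seed=20230603))


@pytest.fixture()
def tiny_manifest():
    return pd.DataFrame(
        {
            "probe_id": ["p1", "p2", "p3", "px"],
            "chrom": ["1", "1", "3", "X"],
            "pos": [100, 250, 37033539, 500],
            "gene": ["", "", "MLH1", ""],
        }
    ).set_index("probe_id")


@pytest.fixture()
def tiny_beta(tiny_manifest):
    vals = pd.DataFrame(
        {"s1": [0.1, 0.5, 0.9, 0.4], "s2": [0.2, 0.6, 0.8, 0.5]},
        index=tiny_manifest.index,
    )
    return BetaMatrix(values=vals)


def make_beta(values: dict, probes=None) -> BetaMatrix:
    """Build a BetaMatrix from a sample -> list-of-betas dict."""
    df = pd.DataFrame(values)
    if probes is not None:
        df.index = pd.Index(probes, name="probe_id")
    return BetaMatrix(values=df)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
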