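import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from salamet.otu_io import ReadMatrix  # noqa: E402


@pytest.fixture
def toy_matrix():
    """3 samples x 3 OTUs with host OTU and known arithmetic."""
    counts = pd.DataFrame(
        [[10, 30, 60], [0, 5, 95], [20, 20, 60]],
        index=["s1", "s2", "s3"],
        columns=["otu_A", "otu_B", "OTU_HOST"],
    )
    meta = pd.DataFrame(
        {"habitat_type": ["restored", "restored", "alternative"],
         "primer": ["18SV9"] * 3},
        index=counts.index)
    return ReadMatrix(counts, meta)


@pytest.fixture
def toy_taxonomy():
    return pd.DataFrame(
        {"taxon": ["A", "B", "Hynobius_yangi"],
         "family": ["Perlidae", "Perlidae", "Hynobiidae"],
         "is_host": [False, False, True]},
        index=pd.Index(["otu_A", "otu_B", "OTU_HOST"], name="otu_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
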