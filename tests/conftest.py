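import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import atlasdecon as ad

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture(scope="session")
def noiseless_atlas():
    """Exact-mixture atlas: whole body is the weighted sum of its parts."""
    return ad.generate_atlas(noise_sd_log=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_profiles(noiseless_atlas):
    matrix, sheet, truth = noiseless_atlas
    grouped = ad.aggregate_replicates(matrix, sheet, ("compartment",))
    profiles = {key[0]: prof for key, prof in grouped.items()}
    whole_body = profiles.pop("whole_body")
    return profiles, whole_body, truth


@pytest.fixture
def toy_profiles():
    """Three hand-built compartment profiles over a 6-gene universe."""
    genes = [f"g{i}" for i in range(6)]

    def prof(name, values):
        return ad.ConditionProfile(
            values=pd.Series(values, index=genes, dtype=float),
            compartment=name, n_replicates=3,
        )

    return {
        "head": prof("head", [100.0, 0.0, 0.0, 10.0, 50.0, 5.0]),
        "gut": prof("gut", [0.0, 200.0, 0.0, 10.0, 55.0, 5.0]),
        "ovaries": prof("ovaries", [0.0, 0.0, 80.0, 10.0, 45.0, 5.0]),
    }


@pytest.fixture
def tiny_matrix():
    genes = ["g1", "g2", "g3"]
    data = pd.DataFrame(
        {
            "s1": [250_000.0, 250_000.0, 500_000.0],
            "s2": [100_000.0, 400_000.0, 500_000.0],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return ad.ExpressionMatrix(data, "TPM")
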