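import numpy as np
import pandas as pd
import pytest

from adniche.abundance import AsvTable
from adniche.hmm import build_profile_hmm


@pytest.fixture
def small_table():
    """4 taxa x 4 samples raw count table."""
    data = pd.DataFrame(
        {
            "s1": [10, 5, 0, 85],
            "s2": [20, 10, 5, 65],
            "s3": [5, 40, 10, 45],
            "s4": [1, 60, 20, 19],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    return AsvTable(data, mode="raw")


@pytest.fixture
def toy_hmm():
    """4-match-state profile from a 3-sequence ungapped alignment."""
    return build_profile_hmm({"a": "ACGT", "b": "ACGT", "c": "ACAT"})


@pytest.fixture
def toy_msa_with_gaps():
    return {
        "r1": "ACGT-A",
        "r2": "ACGTTA",
        "r3": "AC-TTA",
        "r4": "ACGT-A",
    }


def rng(seed=0):
    return np.random.default_rng(seed)
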