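import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from rpoaprof.primers import default_primer_pair
from rpoaprof.synthetic import SimConfig, simulate_reference_library


@pytest.fixture(scope="session")
def pair():
    return default_primer_pair()


@pytest.fixture(scope="session")
def small_library():
    """12-record library, one reference per group (fast all-pairs work)."""
    cfg = SimConfig(seed=101, refs_per_group=(1,) * 12)
    records, _ = simulate_reference_library(cfg)
    return records


@pytest.fixture(scope="session")
def full_library():
    """Default 106-record, 12-group library."""
    cfg = SimConfig(seed=202)
    records, _ = simulate_reference_library(cfg)
    return records


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def plant_substitutions(rng, seq: str, k: int) -> str:
    """Introduce exactly k substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)
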