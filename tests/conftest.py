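import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `naive` importable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_collection(rng: np.random.Generator, max_members=10, max_length=200):
    """A random sequence collection as (identifier, sequence) pairs."""
    n = int(rng.integers(1, max_members + 1))
    members = []
    for j in range(n):
        length = int(rng.integers(1, max_length + 1))
        seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24] * 4 + [0.04]))
        members.append((f"seq{j}", seq))
    return members


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
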