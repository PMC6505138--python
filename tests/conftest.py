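import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import codonmix as cm

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gauss_spec():
    """Truncated-Gaussian spec at the reference scale sigma = 0.009."""
    return cm.solve_mu(0.009)


@pytest.fixture(scope="session")
def comp1(gauss_spec):
    """Exact expected ordered sequence of the weak-bias compartment."""
    return cm.expected_ordered_sequence_exact(gauss_spec)


@pytest.fixture(scope="session")
def comp2():
    """Packaged synthetic stand-in for the strong-bias compartment."""
    return cm.load_packaged_strong_compartment()


@pytest.fixture
def spsum_file(tmp_path):
    """Small hand-built spsum file: 3 genomes with known counts."""
    rng = np.random.default_rng(42)
    counts_a = rng.integers(50, 400, size=64)
    counts_b = rng.integers(0, 30, size=64)
    counts_c = np.full(64, 100)
    lines = [
        "1001:Examplea alpha:12",
        " ".join(map(str, counts_a)),
        "1002:Examplea beta: strain X:3",  # species containing a colon
        " ".join(map(str, counts_b)),
        "1003:Examplea gamma:7",
        " ".join(map(str, counts_c)),
    ]
    p = tmp_path / "fixture.spsum"
    p.write_text("\n".join(lines) + "\n")
    return p, [counts_a, counts_b, counts_c]


def random_frequency_vector(seed: int) -> cm.FrequencyVector:
    rng = np.random.default_rng(seed)
    v = rng.gamma(2.0, size=64)
    return cm.FrequencyVector(v / v.sum())
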