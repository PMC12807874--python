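import numpy as np
import pytest
from hypothesis import settings

from brfscan import SimConfig, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The default seeded breakage-replication/fusion run (seed 1)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def mmbir_sim():
    return simulate(SimConfig(seed=1, mode="mmbir"))


@pytest.fixture(scope="session")
def clean_sim():
    """A noise-free run: breaks spaced well beyond the adjacency
    threshold, no single-strand gaps."""
    return simulate(SimConfig(seed=3, min_dsb_spacing=50_000, nick_prob=0.0))


def random_catalog(rng: np.random.Generator, n: int, span: int = 2_000_000):
    """Random oriented breakpoints on one chromosome for oracle tests."""
    from brfscan import Breakpoint

    positions = rng.integers(1, span, size=n)
    orients = rng.choice(["L", "R"], size=n)
    return [
        Breakpoint("chr1", int(p), str(o), "s", f"j{i}")
        for i, (p, o) in enumerate(zip(positions, orients))
    ]
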