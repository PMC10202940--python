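"""Shared fixtures: small simulated datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from goldenpath.simulate import SimConfig, gen_genome, sim_reads

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_genome() -> str:
    """100 kb uniform genome, fixed seed."""
    return gen_genome(SimConfig(G=100_000, seed=42))


@pytest.fixture(scope="session")
def clean_reads(small_genome):
    """Error-free 20x reads over the small genome."""
    cfg = SimConfig(G=100_000, coverage=20, error_rate=0.0, seed=42,
                    min_length=3000)
    return sim_reads(small_genome, cfg)


@pytest.fixture(scope="session")
def noisy_reads(small_genome):
    """5%-error 20x reads over the small genome."""
    cfg = SimConfig(G=100_000, coverage=20, error_rate=0.05, seed=43,
                    min_length=3000)
    return sim_reads(small_genome, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture()
def seq_factory(rng):
    return lambda n: random_seq(rng, n)
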