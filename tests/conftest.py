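import numpy as np
import pytest

from paleoprof import (
    BriggsParams,
    SampleConfig,
    perfect_alignments,
    random_genome,
    simulate_reads,
)

STANDARD_DAMAGE = BriggsParams(lam=0.3, delta_d=0.4, delta_s=0.01)


@pytest.fixture(scope="session")
def genome30():
    """60 kb synthetic genome at 30% GC."""
    return random_genome("genome30", 60000, 0.30, 101)


@pytest.fixture(scope="session")
def genome50():
    """50 kb synthetic genome at 50% GC."""
    return random_genome("genome50", 50000, 0.50, 102)


@pytest.fixture(scope="session")
def damaged_sample(genome50):
    """A 5000-read damaged sample with truth and true-placement alignments."""
    config = SampleConfig(
        taxa=((genome50, 1.0),),
        n_reads=5000,
        damage=STANDARD_DAMAGE,
        seed=777,
        sample_id="FIX",
    )
    reads, truths = simulate_reads(config)
    alignments = perfect_alignments(reads, truths, {genome50.taxon_id: genome50})
    return reads, truths, alignments


@pytest.fixture
def rng():
    return np.random.default_rng(42)
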