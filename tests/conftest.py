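import numpy as np
import pytest

from utrleader.simulate import SimulationConfig, simulate_repertoire

BASES = "ACGT"


@pytest.fixture(scope="session")
def small_sim():
    """One het subject, two alleles, clean 60:40 variant mixtures."""
    config = SimulationConfig(
        seed=7, n_subjects=1, n_alleles=2, reads_per_allele=120
    )
    return simulate_repertoire(config)


@pytest.fixture(scope="session")
def cohort_sim():
    """Default three-subject cohort, used for cross-subject stages."""
    return simulate_repertoire(SimulationConfig(seed=11))


def random_read_set(rng: np.random.Generator, max_reads=12, max_positions=8):
    """A random small 3'-anchored read set (with occasional N bases)."""
    n = int(rng.integers(1, max_reads + 1))
    reads = []
    for _ in range(n):
        length = int(rng.integers(1, max_positions + 1))
        chars = [
            "N" if rng.random() < 0.08 else BASES[int(rng.integers(0, 4))]
            for _ in range(length)
        ]
        reads.append("".join(chars))
    return reads
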