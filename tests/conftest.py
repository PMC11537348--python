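import numpy as np
import pytest

from hostguard.pml import ReferenceCollection, build_index
from hostguard.simulate import SimulationConfig, generate_genome, simulate_reads

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def brute_force_matching_statistics(read: str, strands: list[str]) -> list[int]:
    """Oracle: for each position, scan every suffix of read[:i+1] directly."""
    values = []
    for i in range(len(read)):
        best = 0
        for start in range(i + 1):
            suffix = read[start : i + 1]
            if "N" in suffix:
                continue
            if any(suffix in s for s in strands):
                best = i + 1 - start
                break  # longest suffix first
        values.append(best)
    return values


def strands_of(refs: ReferenceCollection) -> list[str]:
    from Bio.Seq import reverse_complement

    out = []
    for _, seq in refs:
        out.append(seq)
        out.append(reverse_complement(seq))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def host_genome():
    return generate_genome(8000, seed=11, label="host")


@pytest.fixture(scope="session")
def microbe_genome():
    return generate_genome(8000, seed=12, label="microbe")


@pytest.fixture(scope="session")
def host_index(host_genome):
    return build_index(ReferenceCollection([(host_genome.identifier, host_genome.sequence)]))


@pytest.fixture(scope="session")
def mixture(host_genome, microbe_genome):
    """50/50 error-free labeled mixture of 1000 reads."""
    from hostguard.simulate import mix

    host_reads = simulate_reads(host_genome, SimulationConfig(n_reads=500, seed=21))
    microbe_reads = simulate_reads(microbe_genome, SimulationConfig(n_reads=500, seed=22))
    return mix(host_reads, microbe_reads, 0.5, seed=23)
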