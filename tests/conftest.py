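import numpy as np
import pytest

from chromoforge import synth


@pytest.fixture(scope="session")
def tiny_config():
    return synth.SimConfig(
        n_chromosomes=2,
        chromosome_length=400_000,
        n_scaffolds_per_chromosome=4,
        n_markers=96,
        n_progeny=120,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return synth.simulate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_cross(tiny_genome, tiny_config):
    return synth.simulate_cross(tiny_genome, tiny_config)


def make_testcross_genome(
    n_markers: int = 2,
    cm_positions=(0.0, 10.0),
    length: int = 250_000,
    seed: int = 0,
) -> synth.TrueGenome:
    """A single-chromosome, single-scaffold genome with markers at given cM."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, length)].tobytes().decode()
    cm_per_mb = 50.0
    positions = [int(cm / cm_per_mb * 1e6) for cm in cm_positions]
    assert max(positions) < length
    markers = [
        synth.MarkerTruth(f"M{k + 1:05d}", "chrom_1", p, cm)
        for k, (p, cm) in enumerate(zip(positions, cm_positions))
    ]
    return synth.TrueGenome(
        {"chrom_1": seq},
        {"chrom_1": [("scaffold_0001", 0, length, "+")]},
        markers,
        cm_per_mb,
    )
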