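import numpy as np
import pytest

from satellitome.simdata import FamilySpec, ReadSimConfig, plant_satellites, simulate_reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_specs():
    """Two small families, one W-linked, zero mutation: exact bookkeeping."""
    return [
        FamilySpec("alpha", "ACGTACGTTC" * 3, 60, 60, 2, 0.0, linkage="autosomal"),
        FamilySpec("wbeta", "TTAGGCATCAGGCATT" * 2, 40, 0, 1, 0.0, linkage="W"),
    ]


@pytest.fixture(scope="session")
def tiny_genome(tiny_specs):
    return plant_satellites(tiny_specs, 30_000, seed=11)


@pytest.fixture(scope="session")
def tiny_reads(tiny_genome):
    cfg = ReadSimConfig(n_read_pairs=400, per_base_error_rate=0.0, seed=12,
                        insert_mean=400, insert_sd=30)
    female, male, origins = simulate_reads(tiny_genome, cfg)
    return female, male, origins
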