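import numpy as np
import pytest

from apskat.io import GenotypeMatrix, PhenotypeData
from apskat.synthetic import generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A scaled haplotype panel shared across tests (300 haplotypes, ~250 sites)."""
    return generate_panel(H=300, S=250, region_length=200_000, seed=11)


@pytest.fixture()
def tiny_genotypes():
    """Deterministic 6-sample, 3-variant matrix with rare and common columns."""
    dosages = np.array([
        [0, 1, 2],
        [0, 0, 1],
        [1, 0, 2],
        [0, 0, 1],
        [0, 1, 2],
        [0, 0, 1],
    ], dtype=float)
    return GenotypeMatrix(dosages=dosages,
                          sample_ids=[f"s{i}" for i in range(1, 7)],
                          variant_ids=["v1", "v2", "v3"])


@pytest.fixture()
def tiny_phenotype(tiny_genotypes):
    rng = np.random.default_rng(5)
    return PhenotypeData(values=rng.standard_normal(6),
                         sample_ids=list(tiny_genotypes.sample_ids))
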