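import numpy as np
import pytest

from earmap.formats import GenotypeMatrix, MarkerMap
from earmap.simdata import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulated cross shared across tests."""
    return simulate_cross(SimConfig(seed=1))


@pytest.fixture()
def toy_markers():
    return MarkerMap(
        ["m1", "m2", "m3"], ["5", "5", "5"], [1000, 2000, 3000],
        ["A", "C", "T"], ["G", "T", "C"],
    )


def make_genotypes(dosage, markers=None, ids=None, phase=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    if markers is None:
        markers = MarkerMap(
            [f"m{j}" for j in range(m)], ["5"] * m,
            list(range(1000, 1000 + 1000 * m, 1000)),
            ["A"] * m, ["G"] * m,
        )
    if ids is None:
        ids = [f"i{i}" for i in range(n)]
    return GenotypeMatrix(ids, markers, dosage, phase=phase)


@pytest.fixture()
def geno_factory():
    return make_genotypes
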