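import numpy as np
import pytest

from f2linkage import simulate as sim
from f2linkage.genodata import MarkerGenotypeMatrix


@pytest.fixture
def toy_matrix() -> MarkerGenotypeMatrix:
    """4 individuals x 3 markers with one missing call (A=0, H=1, B=2, -1=missing)."""
    calls = np.array(
        [
            [0, 0, 1],
            [1, 1, 1],
            [2, 2, -1],
            [1, 0, 2],
        ],
        dtype=np.int8,
    )
    return MarkerGenotypeMatrix(["i1", "i2", "i3", "i4"], ["m1", "m2", "m3"], calls)


@pytest.fixture(scope="session")
def dense_population():
    """Error-free F2 population: one 50 cM chromosome, 30 markers, n=200."""
    ch = sim.uniform_chromosome("chr01", 30, 50.0)
    cfg = sim.SimConfig(n_individuals=200, chromosomes=[ch], seed=42)
    matrix, truth = sim.simulate_f2_population(cfg)
    return matrix, truth, ch
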