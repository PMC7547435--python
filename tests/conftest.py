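import numpy as np
import pytest

from wrassepop import GenotypeMatrix, Locus, PopSimConfig, simulate_populations


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """3 individuals x 5 loci on two contigs, one missing call."""
    codes = np.array([
        [0, 1, 2, 0, 1],
        [1, 1, 0, 2, -1],
        [2, 0, 1, 1, 0],
    ], dtype=np.int8)
    loci = [
        Locus("c1", 100), Locus("c1", 900), Locus("c1", 2000),
        Locus("c2", 50), Locus("c2", 1050),
    ]
    return GenotypeMatrix(
        individuals=["i1", "i2", "i3"],
        populations=["A", "A", "B"],
        loci=loci,
        codes=codes,
    )


@pytest.fixture(scope="session")
def two_pop_sim() -> GenotypeMatrix:
    """Two moderately diverged populations, no missing data."""
    return simulate_populations(PopSimConfig(
        n_pops=2, n_per_pop=30, n_loci=2000, target_fst=0.05,
        missing_rate=0.0, seed=11,
    ))
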