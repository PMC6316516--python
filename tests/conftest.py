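import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crossmeth import (
    AlleleRef,
    CrossDesign,
    Population,
    SimParams,
    build_region,
    default_regions,
)

#: single suite-wide base seed; tests derive from it deterministically
SEED = 0


@pytest.fixture(scope="session")
def regions():
    return default_regions()


@pytest.fixture(scope="session")
def region1(regions):
    return regions[0]


@pytest.fixture(scope="session")
def region2(regions):
    return regions[1]


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def toy_region():
    """A 12 bp hand-checkable region with one informative A/G SNP at
    position 6 and shared cytosines at 2 (CpG) and 9 (CpHpG); the
    cytosine at 5 has differing contexts (CpHpG vs CpG) and is not
    shared."""
    col = AlleleRef("toy", "Col", "ACGTCAGTCAGA", flank3="GT")
    ler = AlleleRef("toy", "Ler", "ACGTCGGTCAGA", flank3="GT")
    return build_region(col, ler)


@pytest.fixture
def tiny_design():
    """One-individual-per-population miniature of the full design."""
    return CrossDesign(
        populations=(
            Population("Col", "P", 1, strain="Col"),
            Population("Ler", "P", 1, strain="Ler"),
            Population("F1_ColxLer", "F1", 2, maternal="Col"),
            Population("F1_LerxCol", "F1", 2, maternal="Ler"),
            Population("F2_A", "F2", 4, founder="F1_ColxLer"),
            Population("F2_B", "F2", 4, founder="F1_LerxCol"),
        )
    )


@pytest.fixture
def fast_params():
    return SimParams(coverage=40, seed=SEED)
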