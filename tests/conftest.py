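import pytest

from tmdistort.standin import (
    PRODUCTION_LABELS,
    make_lgr_like_alignment,
    make_receptor_standin,
    tshr_like_numbering,
    tshr_like_sequence,
)
from tmdistort.synthetic_data import HelixSpec, make_bulged_helix, make_ideal_helix, make_kinked_helix


@pytest.fixture(scope="session")
def ideal30():
    return make_ideal_helix(HelixSpec(30))


@pytest.fixture(scope="session")
def kinked30():
    return make_kinked_helix(HelixSpec(30), 30.0, 15)


@pytest.fixture(scope="session")
def bulged30():
    return make_bulged_helix(HelixSpec(30), 15)


@pytest.fixture(scope="session")
def tshr_sequence():
    return tshr_like_sequence()


@pytest.fixture(scope="session")
def tshr_numbering():
    return tshr_like_numbering()


@pytest.fixture(scope="session")
def receptor():
    """Synthetic five-frame receptor trajectory (seed 1) + numbering."""
    return make_receptor_standin(seed=1)


@pytest.fixture(scope="session")
def production_labels():
    return PRODUCTION_LABELS


@pytest.fixture(scope="session")
def lgr_alignment():
    """Synthetic 52-sequence LGR-like alignment (seed 0) + groups."""
    return make_lgr_like_alignment(seed=0)
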