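import numpy as np
import pytest

from remfrag.clusters import adjacency_from_positions
from remfrag.hypnogram import Hypnogram
from remfrag.io import CH_NAMES_19, montage_positions
from remfrag.simulate import CohortConfig


@pytest.fixture(scope="session")
def config():
    """Default synthetic-cohort configuration (small subject count)."""
    return CohortConfig(n_subjects=4, seed=123)


@pytest.fixture(scope="session")
def adjacency():
    pos = montage_positions()
    return adjacency_from_positions(pos, list(CH_NAMES_19))


@pytest.fixture
def rng():
    return np.random.default_rng(987)


def make_hypnogram(stages, lights_off=0, lights_on=None):
    return Hypnogram(stages=tuple(stages), lights_off_index=lights_off,
                     lights_on_index=lights_on)
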