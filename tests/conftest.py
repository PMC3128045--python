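import numpy as np
import pytest

from physaiso import datasets
from physaiso.sexual_isolation import MateChoiceTrial, PairTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def study_tree():
    return datasets.species_tree()


@pytest.fixture
def acuta_pomilia_table():
    return datasets.acuta_pomilia_pair_table()


def make_trial(counts, pop_a="a", pop_b="b", n_per_type=None):
    """Build a MateChoiceTrial whose table has the given (aa, ab, ba, bb)."""
    aa, ab, ba, bb = counts
    if n_per_type is None:
        n_per_type = max(aa + ab, ba + bb, 1)
    events = (
        [(pop_a, pop_a)] * aa
        + [(pop_a, pop_b)] * ab
        + [(pop_b, pop_a)] * ba
        + [(pop_b, pop_b)] * bb
    )
    return MateChoiceTrial(
        pop_a=pop_a, pop_b=pop_b, events=tuple(events), n_per_type=n_per_type
    )


@pytest.fixture
def trial_factory():
    return make_trial
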