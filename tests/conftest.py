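"""Shared fixtures: synthetic reference data and learnt profiles.

Everything is generated programmatically and seeded; the expensive
profile learning is session-scoped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scbinsim import (
    ClassifierConfig,
    PseudocountModel,
    default_fixture_spec,
    generate_reference_fixture,
)


@pytest.fixture(scope="session")
def fixture_reference():
    """30-gene reference matrix (10 per category) with ground-truth labels."""
    spec = default_fixture_spec(n_cells=2000, seed=11)
    matrix, labels = generate_reference_fixture(spec)
    return matrix, labels, spec


@pytest.fixture(scope="session")
def fixture_matrix(fixture_reference):
    return fixture_reference[0]


@pytest.fixture(scope="session")
def fixture_labels(fixture_reference):
    return fixture_reference[1]


@pytest.fixture(scope="session")
def learned_profiles(fixture_matrix):
    """Profiles learnt from the fixture reference (seeded)."""
    model = PseudocountModel(fixture_matrix, config=ClassifierConfig(random_seed=3))
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_counts():
    return pd.DataFrame(
        [[10, 0, 5, 1], [0, 3, 2, 7], [4, 4, 0, 2]],
        index=["c1", "c2", "c3"],
        columns=["g1", "g2", "g3", "g4"],
    )
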