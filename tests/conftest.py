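"""Shared fixtures: phantoms and small tracked corpora, built once."""

import numpy as np
import pytest

from cornn.phantom import make_default_subject
from cornn.reference_tracker import TrackerConfig, make_chunks, track_reference


@pytest.fixture(scope="session")
def subject():
    """Default three-bundle phantom (40^3 voxels at 2 mm)."""
    return make_default_subject(seed=1)


@pytest.fixture(scope="session")
def val_subject():
    """Second subject (different texture/noise realization)."""
    return make_default_subject(seed=2)


@pytest.fixture(scope="session")
def reference_tractogram(subject):
    """Small reference tractogram on the default phantom."""
    cfg = TrackerConfig(n_streamlines=300, seed=11)
    return track_reference(subject, cfg)


@pytest.fixture(scope="session")
def reference_chunks(reference_tractogram):
    return make_chunks(reference_tractogram, chunk_size=64, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
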