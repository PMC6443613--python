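"""Shared fixtures: small phantom sets and pre-trained tiny models.

Heavy artifacts (trained segmenter, auto-encoder) are session-scoped so
the whole suite trains each network once.
"""

import numpy as np
import pytest

from myotriage import CohortSpec, TriplanarSegmenter, ConvAutoencoder
from myotriage.autoencoder import sample_training_patches
from myotriage.phantom import generate_phantom_volume, sample_phantom_params

# fixture-scale network settings: small patches, few epochs
SEG_CONFIG = dict(
    patch_edge=9, epochs=3, samples_per_volume=1500, stride=1, random_state=7
)


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec(n_patients=8, seed=11)


@pytest.fixture(scope="session")
def phantom_set(cohort_spec):
    """Six phantoms (alternating labels) with their true masks."""
    vols, masks, labels = [], [], []
    for i in range(6):
        params = sample_phantom_params(1000 + i, cohort_spec)
        label = i % 2 == 0
        v, m = generate_phantom_volume(params, label, cohort_spec)
        vols.append(v)
        masks.append(m)
        labels.append(label)
    return vols, masks, labels


@pytest.fixture(scope="session")
def trained_segmenter(phantom_set):
    """Tiny two-stream CNN trained on the first four phantoms."""
    vols, masks, _ = phantom_set
    seg = TriplanarSegmenter(**SEG_CONFIG)
    seg.fit(vols[:4], masks[:4])
    return seg


@pytest.fixture(scope="session")
def cae_patches(phantom_set):
    vols, masks, _ = phantom_set
    return sample_training_patches(vols[:4], masks[:4], 500, seed=5, patch_size=4)


@pytest.fixture(scope="session")
def trained_cae(cae_patches):
    return ConvAutoencoder(epochs=5, random_state=3).fit(cae_patches)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
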