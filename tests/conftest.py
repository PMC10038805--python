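import warnings

import numpy as np
import pandas as pd
import pytest

import braincast as bc

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(autouse=True)
def _quiet_pipeline_warnings():
    """The reduced desk-scale problems trip benign pipeline warnings
    (PCA component clipping, constant test-fold predictions); tests that
    care about a warning assert it explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def tiny_stimulus():
    return bc.generate_stimulus(n_words=300, word_rate=2.54, n_stories=2, seed=101)


@pytest.fixture(scope="session")
def tiny_activations(tiny_stimulus):
    return bc.generate_layered_embeddings(tiny_stimulus, n_layers=5, dim=4, seed=102)


def planted_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "voxel_id",
            "planted_distance",
            "planted_layer",
            "planted_component",
            "signal_gain",
        ],
    )


@pytest.fixture(scope="session")
def small_planted_dataset():
    """A compact planted dataset shared by pipeline tests: 6 subjects,
    8 voxels (4 planted at distances 6 and 10, layer 2), ~1,200 words."""
    stimulus = bc.generate_stimulus(1200, 2.54, 2, seed=111)
    acts = bc.generate_layered_embeddings(stimulus, n_layers=5, dim=4, seed=112)
    plants = planted_table(
        [(0, 6, 2, "full", 5.0), (1, 6, 2, "full", 5.0),
         (2, 10, 2, "full", 5.0), (3, 10, 2, "full", 5.0)]
    )
    spec = bc.SyntheticSpec(n_subjects=6, n_voxels=8, voxel_plants=plants, seed=113)
    runs, truth = bc.generate_bold(stimulus, acts, spec)
    return dict(stimulus=stimulus, activations=acts, spec=spec, runs=runs, truth=truth)
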