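import hashlib

import numpy as np
import pandas as pd
import pytest

from morphospace import (
    BranchSpec,
    EmbeddingConfig,
    ParcelMatrix,
    fit_morphospace,
    loo_predictability,
    make_branch_maps,
    make_toy_atlas,
)
from morphospace.embedding import Morphospace


@pytest.fixture(scope="session")
def toy_atlas_small():
    """6x6x6 grid tiled into 8 parcels; both hemispheres present."""
    return make_toy_atlas((6, 6, 6), 8, seed=0)


@pytest.fixture(scope="session")
def default_dataset():
    """The default noiseless branch collection (60 maps x 120 parcels)."""
    spec = BranchSpec()
    atlas, centroids = make_toy_atlas((12, 12, 12), spec.n_parcels, seed=spec.seed)
    ds = make_branch_maps(spec, centroids)
    return spec, atlas, ds


@pytest.fixture(scope="session")
def default_space(default_dataset):
    _, _, ds = default_dataset
    return fit_morphospace(ds.parcel_matrix, EmbeddingConfig(seed=0))


@pytest.fixture(scope="session")
def default_loo(default_space, default_dataset):
    _, _, ds = default_dataset
    return loo_predictability(default_space, ds.parcel_matrix, thresholded=False)


def make_fake_space(coords: np.ndarray, matrix: ParcelMatrix) -> Morphospace:
    """A Morphospace with hand-set coordinates (no UMAP) for geometry tests."""
    frame = pd.DataFrame(np.asarray(coords, dtype=float), index=matrix.map_ids,
                         columns=[f"dim_{i + 1}" for i in range(np.shape(coords)[1])])
    checksum = hashlib.sha256(frame.to_numpy().tobytes()).hexdigest()
    return Morphospace(coordinates=frame, transformer=None,
                       config=EmbeddingConfig(seed=0),
                       training_checksum=checksum, training_matrix=matrix)


@pytest.fixture
def fake_space_factory():
    return make_fake_space
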