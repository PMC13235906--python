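"""Shared fixtures.

Heavy fixtures (the 720-image synthetic dataset and the four trained
fusion models) are session-scoped so the end-to-end and saliency tests can
share one training run per fusion kind.
"""

import numpy as np
import pytest

from taxovision import syndata
from taxovision.dataqc import stratified_split
from taxovision.taxonomy import build_taxonomy
from taxovision.train import FUSIONS, TaxonomicClassifier

TOY_TRIPLES = [
    ("FamA", "GenA1", "GenA1 sp1"),
    ("FamA", "GenA1", "GenA1 sp2"),
    ("FamA", "GenA2", "GenA2 sp3"),
    ("FamB", "GenB1", "GenB1 sp4"),
]

# study conditions for the end-to-end smoke run: 3 families / 6 genera /
# 12 species, 60 lab-regime images per species at 32 px
SMOKE_SPEC = syndata.SyntheticSpec(
    n_families=3, n_genera=6, n_species=12, images_per_species=60,
    image_size=32, seed=7)
SMOKE_EPOCHS = 12


@pytest.fixture(scope="session")
def toy_tree():
    """2 families / 3 genera / 4 species."""
    return build_taxonomy(TOY_TRIPLES)


@pytest.fixture(scope="session")
def smoke_dataset():
    return syndata.generate_dataset(SMOKE_SPEC)


@pytest.fixture(scope="session")
def smoke_split(smoke_dataset):
    assignment = stratified_split(smoke_dataset.manifest, seed=7)
    masks = {}
    for name in ("train", "val", "test"):
        ids = set(assignment.subset_ids(name))
        masks[name] = smoke_dataset.manifest["path"].isin(ids).to_numpy()
    return masks


@pytest.fixture(scope="session")
def trained_models(smoke_dataset, smoke_split):
    """One trained classifier per fusion kind, identical conditions."""
    X = smoke_dataset.images[smoke_split["train"]]
    y = smoke_dataset.labels[smoke_split["train"]]
    models = {}
    for fusion in FUSIONS:
        clf = TaxonomicClassifier(
            taxonomy=smoke_dataset.tree, fusion=fusion, embedding_dim=64,
            base_channels=8, stage1_epochs=SMOKE_EPOCHS, stage2_epochs=0,
            batch_size=32, random_state=0)
        clf.fit(X, y)
        models[fusion] = clf
    return models


def random_probability_rows(rng: np.random.Generator, n: int, k: int
                            ) -> np.ndarray:
    """(n, k) rows on the simplex with uniformly distributed argmax."""
    return rng.dirichlet(np.ones(k), size=n)


def one_hot(index: int, k: int) -> np.ndarray:
    v = np.full(k, 1e-9)
    v[index] = 1.0 - 1e-9 * (k - 1)
    return v
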