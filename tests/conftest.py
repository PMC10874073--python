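"""Shared fixtures: deterministic RNGs, small synthetic datasets, and one
session-scoped overfitting run reused by the model and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import glcndta as g
from glcndta.model import ModelConfig, train

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def synthetic_dir(tmp_path_factory):
    """A small noisy synthetic benchmark directory (generator defaults)."""
    path = tmp_path_factory.mktemp("synth") / "bench"
    g.make_synthetic_dataset(path, seed=11)
    return path


@pytest.fixture(scope="session")
def overfit_run(tmp_path_factory):
    """Noise-free 50-pair fixture trained for 300 epochs with the default
    2-layer / d_model=128 model (the learning-capacity check).

    Session-scoped: the run takes a few minutes and several tests inspect
    different aspects of the same trajectory.
    """
    path = tmp_path_factory.mktemp("overfit") / "bench"
    dataset = g.make_synthetic_dataset(path, n_drugs=10, n_proteins=5, noise_sd=0.0, seed=7)
    config = ModelConfig(epochs=300, seed=0, val_fraction=0.0)
    state, history = train(dataset, config)
    return dataset, state, history


def toy_protein(seq: str, seed: int = 0) -> g.ProteinGraph:
    cmap = g.make_synthetic_contact_map(len(seq), seed=seed)
    pssm = g.make_synthetic_pssm(len(seq), seed=seed)
    return g.build_protein_graph(seq, cmap, pssm)


@pytest.fixture
def toy_pairs():
    """Three small drug/protein graph pairs of different sizes."""
    mols = [g.build_molecule_graph(s) for s in ("CCO", "c1ccccc1O", "CC(=O)Oc1ccccc1C(=O)O")]
    prots = [toy_protein(s, i) for i, s in enumerate(("ACDEFGHIK", "MNPQRSTVWYACD", "GAVLI"))]
    return mols, prots
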