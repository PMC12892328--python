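"""Shared fixtures: synthetic structures and small planted datasets."""

import numpy as np
import pytest

from pkagraph.graph_builder import build_dataset
from pkagraph.structure_io import attach_dipoles
from pkagraph.synthetic_fixtures import (
    FixtureSpec,
    make_planted_dataset,
    make_toy_protein,
    reference_label_table,
)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A proper rotation matrix (det +1) from a random orthogonal factor."""
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture(scope="session")
def toy_structure():
    """An 8-residue peptide (4 ionizable + spacers) with dipoles attached."""
    spec = FixtureSpec(n_residues=8, seed=11)
    structure, dipoles = make_toy_protein(spec, source_id="fix8")
    structure, _ = attach_dipoles(structure, dipoles)
    return structure


@pytest.fixture(scope="session")
def toy_graphs(toy_structure):
    """Unnormalized residue graphs built from the toy peptide at 9 A."""
    labels = reference_label_table(toy_structure)
    graphs, skipped = build_dataset(toy_structure, labels, radius=9.0)
    assert not skipped
    return graphs


@pytest.fixture(scope="session")
def planted_small():
    """A small planted-mechanism dataset for fast training tests."""
    graphs, record = make_planted_dataset(n_graphs=120, noise_sd=0.3, seed=21)
    return graphs, record
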