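"""Shared fixtures: toy complexes and their derived surface objects."""

from __future__ import annotations

import pytest

from prise.repository import build_repository
from prise.surface import (RULE_VDW_05, compute_asa, find_surface_neighbors,
                           label_interface_residues)
from prise.synthetic import ToyComplexSpec, generate_toy_complex


@pytest.fixture(scope="session")
def toy():
    """A 12-residue two-chain complex with a planted 6-residue patch."""
    complex_model, pdb_text, truth = generate_toy_complex(
        ToyComplexSpec(seed=11))
    return complex_model, pdb_text, truth


@pytest.fixture(scope="session")
def toy_complex(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_chain(toy_complex):
    return toy_complex.chains[0]


@pytest.fixture(scope="session")
def toy_asa(toy_chain):
    return compute_asa(toy_chain)


@pytest.fixture(scope="session")
def toy_graph(toy_chain, toy_asa):
    return find_surface_neighbors(toy_chain, toy_asa)


@pytest.fixture(scope="session")
def toy_labels(toy_complex):
    return label_interface_residues(toy_complex, RULE_VDW_05)


@pytest.fixture(scope="session")
def toy_repo():
    """Repository built from two toy complexes (different seeds)."""
    complexes = [generate_toy_complex(ToyComplexSpec(seed=s))[0]
                 for s in (21, 22)]
    return build_repository(complexes)
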