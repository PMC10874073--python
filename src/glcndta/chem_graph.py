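"""Molecule graphs from SMILES.

A drug molecule is represented as an undirected graph whose nodes are the
heavy atoms and whose edges are the covalent bonds, with a self-loop on
every node so that each atom aggregates its own features during
convolution.  Each atom carries a 78-dimensional binary feature vector:

======================  =====  ============================================
block                   width  content
======================  =====  ============================================
atom symbol             44     one-hot over a fixed 44-symbol vocabulary
                               (43 named elements + a catch-all slot)
degree                  11     one-hot of the heavy-atom neighbour count,
                               0..10, values above 10 clamp to the last slot
total hydrogens         11     one-hot of the total H count, 0..10, clamped
implicit hydrogens      11     one-hot of the implicit H count, 0..10, clamped
aromatic flag            1     1 if the atom is aromatic
======================  =====  ============================================

The vocabulary is the one used throughout the graph-DTA literature; the
catch-all slot makes featurization total on any parseable SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # quiet rdkit parse warnings; errors surface as None

__all__ = [
    "ATOM_SYMBOLS",
    "ATOM_FEATURE_DIM",
    "AtomDescriptor",
    "MoleculeGraph",
    "SmilesParseError",
    "featurize_atom",
    "build_molecule_graph",
    "read_smiles_file",
]

#: Fixed atom-symbol vocabulary (43 named elements + ``"Unknown"`` catch-all).
ATOM_SYMBOLS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
)

_COUNT_SLOTS = 11  # one-hot range 0..10 for degree / total-H / implicit-H

#: Total atom feature width: 44 + 11 + 11 + 11 + 1.
ATOM_FEATURE_DIM = len(ATOM_SYMBOLS) + 3 * _COUNT_SLOTS + 1


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class AtomDescriptor:
    """The atom attributes that enter the feature vector."""

    symbol: str
    degree: int
    total_h: int
    implicit_h: int
    aromatic: bool


@dataclass(frozen=True)
class MoleculeGraph:
    """A featurized molecule: node features (N, 78) and binary adjacency.

    The adjacency is symmetric with a unit diagonal (self-loops).
    """

    smiles: str
    node_features: np.ndarray
    adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def _onehot_count(value: int) -> np.ndarray:
    v = np.zeros(_COUNT_SLOTS)
    v[min(max(int(value), 0), _COUNT_SLOTS - 1)] = 1.0
    return v


def featurize_atom(atom: AtomDescriptor) -> np.ndarray:
    """Encode one atom as the 78-dimensional binary feature vector.

    Out-of-vocabulary symbols map to the catch-all slot; counts above 10
    clamp to the last slot of their block.  The function is total on any
    descriptor.
    """
    symbol_block = np.zeros(len(ATOM_SYMBOLS))
    try:
        symbol_block[ATOM_SYMBOLS.index(atom.symbol)] = 1.0
    except ValueError:
        symbol_block[-1] = 1.0
    return np.concatenate(
        [
            symbol_block,
            _onehot_count(atom.degree),
            _onehot_count(atom.total_h),
            _onehot_count(atom.implicit_h),
            [1.0 if atom.aromatic else 0.0],
        ]
    )


def _describe(atom: Chem.Atom) -> AtomDescriptor:
    return AtomDescriptor(
        symbol=atom.GetSymbol(),
        degree=atom.GetDegree(),
        total_h=atom.GetTotalNumHs(),
        implicit_h=atom.GetNumImplicitHs(),
        aromatic=atom.GetIsAromatic(),
    )


def build_molecule_graph(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Nodes are heavy atoms in rdkit's atom-index order; hydrogens appear only
    through the H-count features.  Every covalent bond contributes the two
    directed entries (i, j) and (j, i); the diagonal is forced to one.

    Raises
    ------
    SmilesParseError
        If rdkit cannot parse ``smiles``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    features = np.stack([featurize_atom(_describe(a)) for a in mol.GetAtoms()])
    adjacency = np.eye(n)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = 1.0
        adjacency[j, i] = 1.0
    return MoleculeGraph(smiles=smiles, node_features=features, adjacency=adjacency)


def read_smiles_file(path) -> list[str]:
    """Read SMILES one per line, skipping blanks and ``#`` comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out
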