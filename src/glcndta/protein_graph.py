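"""Protein graphs from sequence + contact map + PSSM.

Residues are nodes; two residues are connected when their predicted
contact probability, symmetrized by an elementwise maximum with the
transpose, reaches the 0.5 threshold.  Self-loops are always present.

Each residue node carries a 54-dimensional feature vector:

======================  =====  ============================================
block                   width  content
======================  =====  ============================================
residue symbol          21     one-hot over the 20 canonical residues + 'X'
PSSM row                21     position-specific scores for the 21 classes
group flags              5     aliphatic / aromatic / polar-neutral /
                               acidic / basic
weight                   1     residue mass, min-max normalized
pKa / pKb / pKx / pI     4     dissociation constants (-COOH, -NH3, side
                               chain) and isoelectric point, normalized
hydrophobicity           2     at pH 2 and pH 7, normalized
======================  =====  ============================================

The physicochemical constants are the standard published per-residue
tables, frozen here so the featurizer is fully deterministic.  Scalars are
min-max normalized over the 20 canonical residues; the unknown residue 'X'
receives the column mean of the normalized values.

The package does not predict contact maps or compute alignment-based
PSSMs: both arrive as dense whitespace-delimited matrix files
(``<protein_id>.cmap`` / ``<protein_id>.pssm``).  Any real-valued (N, 21)
matrix is accepted as a PSSM — probability- or log-odds-scaled.
:func:`pseudo_pssm` provides a smoothed sequence-only stand-in when no
alignment-derived matrix exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RESIDUES",
    "RESIDUE_FEATURE_DIM",
    "ContactMap",
    "PSSM",
    "ProteinGraph",
    "threshold_contact_map",
    "featurize_residue",
    "build_protein_graph",
    "pseudo_pssm",
    "read_matrix_file",
    "write_matrix_file",
]

#: Canonical residues in alphabetical one-letter order, plus 'X' (unknown).
RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY" + "X"

#: Total residue feature width: 21 + 21 + 5 + 1 + 4 + 2.
RESIDUE_FEATURE_DIM = 54

_ALIPHATIC = set("AILMV")
_AROMATIC = set("FWY")
_POLAR_NEUTRAL = set("CNQST")
_ACIDIC = set("DE")
_BASIC = set("HKR")

# columns: weight, pKa(-COOH), pKb(-NH3), pKx(side chain), pI,
#          hydrophobicity pH2, hydrophobicity pH7
_PHYSCHEM: dict[str, tuple[float, ...]] = {
    "A": (71.0788, 2.34, 9.69, 0.00, 6.00, 47.0, 41.0),
    "C": (103.1388, 1.96, 10.28, 8.18, 5.07, 52.0, 49.0),
    "D": (115.0886, 1.88, 9.60, 3.65, 2.77, -18.0, -55.0),
    "E": (129.1155, 2.19, 9.67, 4.25, 3.22, 8.0, -31.0),
    "F": (147.1766, 1.83, 9.13, 0.00, 5.48, 92.0, 100.0),
    "G": (57.0519, 2.34, 9.60, 0.00, 5.97, 0.0, 0.0),
    "H": (137.1411, 1.82, 9.17, 6.00, 7.59, -42.0, 8.0),
    "I": (113.1594, 2.36, 9.60, 0.00, 6.02, 100.0, 99.0),
    "K": (128.1741, 2.18, 8.95, 10.53, 9.74, -37.0, -23.0),
    "L": (113.1594, 2.36, 9.60, 0.00, 5.98, 100.0, 97.0),
    "M": (131.1926, 2.28, 9.21, 0.00, 5.74, 74.0, 74.0),
    "N": (114.1038, 2.02, 8.80, 0.00, 5.41, -41.0, -28.0),
    "P": (97.1167, 1.99, 10.60, 0.00, 6.30, -46.0, -46.0),
    "Q": (128.1307, 2.17, 9.13, 0.00, 5.65, -18.0, -10.0),
    "R": (156.1875, 2.17, 9.04, 12.48, 10.76, -26.0, -14.0),
    "S": (87.0782, 2.21, 9.15, 0.00, 5.68, -7.0, -5.0),
    "T": (101.1051, 2.09, 9.10, 0.00, 5.60, 13.0, 13.0),
    "V": (99.1326, 2.32, 9.62, 0.00, 5.96, 79.0, 76.0),
    "W": (186.2132, 2.83, 9.39, 0.00, 5.89, 84.0, 97.0),
    "Y": (163.1760, 2.20, 9.11, 10.07, 5.66, 49.0, 63.0),
}


def _normalized_physchem() -> dict[str, np.ndarray]:
    raw = np.array([_PHYSCHEM[aa] for aa in RESIDUES[:20]])
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    scaled = (raw - lo) / (hi - lo)
    table = {aa: scaled[i] for i, aa in enumerate(RESIDUES[:20])}
    table["X"] = scaled.mean(axis=0)
    return table


_PHYSCHEM_SCALED = _normalized_physchem()


@dataclass(frozen=True)
class ContactMap:
    """Residue-residue contact probabilities, square with entries in [0, 1]."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"contact map must be square, got shape {p.shape}")
        if np.any(p < 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
            raise ValueError("contact probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return self.probabilities.shape[0]


@dataclass(frozen=True)
class PSSM:
    """Per-position residue scores, shape (N, 21)."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 2 or s.shape[1] != len(RESIDUES):
            raise ValueError(
                f"PSSM must have {len(RESIDUES)} columns, got shape {s.shape}"
            )
        if not np.all(np.isfinite(s)):
            raise ValueError("PSSM entries must be finite")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class ProteinGraph:
    """A featurized protein: node features (N, 54) and contact adjacency."""

    sequence: str
    node_features: np.ndarray
    adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def threshold_contact_map(cmap: ContactMap, tau: float = 0.5) -> np.ndarray:
    """Binarize a contact-probability matrix into a graph adjacency.

    The matrix is symmetrized by the elementwise maximum with its
    transpose, entries ``>= tau`` become contacts, and the diagonal is
    forced to one (self-loops).  The comparison is inclusive, so raising
    ``tau`` never adds an off-diagonal contact.
    """
    p = cmap.probabilities
    sym = np.maximum(p, p.T)
    adj = (sym >= tau).astype(np.float64)
    np.fill_diagonal(adj, 1.0)
    return adj


def featurize_residue(aa: str, pssm_row: np.ndarray) -> np.ndarray:
    """Encode one residue position as the 54-dimensional feature vector."""
    if aa not in RESIDUES:
        raise ValueError(f"unknown residue letter {aa!r}")
    pssm_row = np.asarray(pssm_row, dtype=np.float64)
    if pssm_row.shape != (len(RESIDUES),):
        raise ValueError(f"PSSM row must have length {len(RESIDUES)}")
    onehot = np.zeros(len(RESIDUES))
    onehot[RESIDUES.index(aa)] = 1.0
    flags = np.array(
        [
            aa in _ALIPHATIC,
            aa in _AROMATIC,
            aa in _POLAR_NEUTRAL,
            aa in _ACIDIC,
            aa in _BASIC,
        ],
        dtype=np.float64,
    )
    return np.concatenate([onehot, pssm_row, flags, _PHYSCHEM_SCALED[aa]])


def build_protein_graph(sequence: str, cmap: ContactMap, pssm: PSSM) -> ProteinGraph:
    """Assemble a :class:`ProteinGraph` from aligned sequence, cmap and PSSM."""
    n = len(sequence)
    if not (n == len(cmap) == len(pssm)):
        raise ValueError(
            "length mismatch: sequence has "
            f"{n} residues, contact map {len(cmap)}, PSSM {len(pssm)}"
        )
    if n == 0:
        raise ValueError("empty protein sequence")
    features = np.stack(
        [featurize_residue(aa, pssm.scores[i]) for i, aa in enumerate(sequence)]
    )
    return ProteinGraph(
        sequence=sequence,
        node_features=features,
        adjacency=threshold_contact_map(cmap),
    )


def pseudo_pssm(sequence: str, pseudocount: float = 0.1) -> PSSM:
    """Sequence-only PSSM fallback: smoothed one-hot rows.

    Row i is ``(onehot(sequence[i]) + c) / (1 + 21 c)`` with pseudocount
    ``c > 0``; rows sum to one.  In the ``c -> 0`` limit the row is the
    residue one-hot.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    k = len(RESIDUES)
    rows = np.full((len(sequence), k), pseudocount)
    for i, aa in enumerate(sequence):
        if aa not in RESIDUES:
            raise ValueError(f"unknown residue letter {aa!r}")
        rows[i, RESIDUES.index(aa)] += 1.0
    return PSSM(rows / (1.0 + k * pseudocount))


def read_matrix_file(path) -> np.ndarray:
    """Read a whitespace-delimited dense matrix text file."""
    m = np.loadtxt(path, ndmin=2)
    return np.asarray(m, dtype=np.float64)


def write_matrix_file(path, matrix: np.ndarray, fmt: str = "%.6f") -> None:
    np.savetxt(path, np.asarray(matrix), fmt=fmt)
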