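"""Benchmark-folder I/O.

The interchange format follows the DeepDTA-style benchmark convention:

* ``ligands.json``   — drug id -> SMILES (insertion order = matrix rows)
* ``proteins.json``  — protein id -> amino-acid sequence (= matrix columns);
  a ``proteins.fasta`` file is accepted in its place
* ``affinity.txt``   — dense drugs x proteins matrix, whitespace-delimited,
  missing measurements as ``nan``
* ``folds/fold_<k>.json`` — JSON lists of record indices partitioning the
  records (records are the non-NaN cells in row-major order)
* ``<protein_id>.cmap`` / ``<protein_id>.pssm`` — dense whitespace matrix
  files with the contact probabilities and PSSM of each protein.

Affinities may be stored already on model scale (pKd / KIBA score) or as
raw Kd in nM; ``read_benchmark(..., kd_to_pkd=True)`` applies the pKd
transform while loading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_graph import MoleculeGraph, build_molecule_graph
from .metrics import pkd_transform
from .protein_graph import (
    PSSM,
    ContactMap,
    ProteinGraph,
    build_protein_graph,
    read_matrix_file,
)

__all__ = [
    "AffinityRecord",
    "ProteinEntry",
    "AffinityDataset",
    "read_benchmark",
    "read_fasta",
    "load_entity_graphs",
]


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences from FASTA, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    protein_id: str
    affinity: float


@dataclass(frozen=True)
class ProteinEntry:
    sequence: str
    cmap_path: Path
    pssm_path: Path


@dataclass
class AffinityDataset:
    """Aligned drug/protein tables, affinity records and fold assignments."""

    ligands: dict[str, str]
    proteins: dict[str, ProteinEntry]
    records: list[AffinityRecord]
    folds: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records])

    def molecule_graph(self, drug_id: str) -> MoleculeGraph:
        return build_molecule_graph(self.ligands[drug_id])

    def protein_graph(self, protein_id: str) -> ProteinGraph:
        entry = self.proteins[protein_id]
        cmap = ContactMap(read_matrix_file(entry.cmap_path))
        pssm = PSSM(read_matrix_file(entry.pssm_path))
        return build_protein_graph(entry.sequence, cmap, pssm)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing benchmark file: {path}")
    return path


def read_benchmark(directory, kd_to_pkd: bool = False) -> AffinityDataset:
    """Load a benchmark-layout directory into an :class:`AffinityDataset`.

    NaN cells of the affinity matrix are dropped; every remaining cell
    becomes one record, enumerated row-major (drug-major).  With
    ``kd_to_pkd`` the matrix is interpreted as raw Kd in nM and
    transformed to pKd.
    """
    directory = Path(directory)
    with open(_require(directory / "ligands.json")) as fh:
        ligands: dict[str, str] = json.load(fh)
    if (directory / "proteins.json").exists():
        with open(directory / "proteins.json") as fh:
            sequences: dict[str, str] = json.load(fh)
    elif (directory / "proteins.fasta").exists():
        sequences = read_fasta(directory / "proteins.fasta")
    else:
        raise FileNotFoundError(f"missing benchmark file: {directory / 'proteins.json'}")

    proteins: dict[str, ProteinEntry] = {}
    for pid, seq in sequences.items():
        proteins[pid] = ProteinEntry(
            sequence=seq,
            cmap_path=_require(directory / f"{pid}.cmap"),
            pssm_path=_require(directory / f"{pid}.pssm"),
        )

    matrix = np.loadtxt(_require(directory / "affinity.txt"), ndmin=2)
    if matrix.shape != (len(ligands), len(sequences)):
        raise ValueError(
            f"affinity.txt has shape {matrix.shape}, expected "
            f"({len(ligands)} drugs, {len(sequences)} proteins)"
        )

    records: list[AffinityRecord] = []
    drug_ids = list(ligands)
    protein_ids = list(sequences)
    for i, did in enumerate(drug_ids):
        for j, pid in enumerate(protein_ids):
            value = matrix[i, j]
            if np.isnan(value):
                continue
            if kd_to_pkd:
                value = pkd_transform(value)
            records.append(AffinityRecord(did, pid, float(value)))

    folds = _read_folds(directory / "folds", len(records))
    return AffinityDataset(ligands=ligands, proteins=proteins, records=records, folds=folds)


def _read_folds(fold_dir: Path, n_records: int) -> list[list[int]]:
    if not fold_dir.is_dir():
        return []
    folds: list[list[int]] = []
    for path in sorted(fold_dir.glob("fold_*.json")):
        with open(path) as fh:
            folds.append([int(i) for i in json.load(fh)])
    seen: set[int] = set()
    for k, fold in enumerate(folds):
        overlap = seen.intersection(fold)
        if overlap:
            raise ValueError(f"fold {k} overlaps earlier folds on indices {sorted(overlap)[:5]}")
        seen.update(fold)
    if folds and seen != set(range(n_records)):
        raise ValueError(
            f"folds cover {len(seen)} of {n_records} record indices; "
            "they must partition all records"
        )
    return folds


def load_entity_graphs(
    dataset: AffinityDataset,
) -> tuple[dict[str, MoleculeGraph], dict[str, ProteinGraph]]:
    """Featurize every unique drug and protein once (training-time cache)."""
    mols = {did: dataset.molecule_graph(did) for did in dataset.ligands}
    prots = {pid: dataset.protein_graph(pid) for pid in dataset.proteins}
    return mols, prots
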