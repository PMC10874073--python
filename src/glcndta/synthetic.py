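"""Synthetic benchmark generator.

Emulates a small DeepDTA-style affinity benchmark so the whole pipeline
(featurization, graph learning, training, evaluation) is exercisable
without any download:

* drugs are sampled from a packaged list of curated drug-like SMILES
  (8-40 heavy atoms, all rdkit-parseable);
* proteins are random sequences over the 20 canonical residues with
  banded synthetic contact maps (near-diagonal contacts plus sparse
  long-range ones, mimicking secondary-structure locality) and Dirichlet
  PSSM rows;
* affinities are a planted linear function of interpretable entity
  statistics — drug heavy-atom count and aromatic fraction, protein
  contact density and hydrophobic fraction — min-max rescaled into the
  Davis-like pKd range [5, 11], plus optional Gaussian measurement noise.

Everything is reproducible from a single seed, and the written directory
round-trips through :func:`glcndta.data.read_benchmark` losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._smiles_library import DRUG_SMILES
from .chem_graph import build_molecule_graph
from .data import AffinityDataset, read_benchmark
from .protein_graph import PSSM, RESIDUES, ContactMap, threshold_contact_map, write_matrix_file

__all__ = [
    "DRUG_SMILES",
    "make_synthetic_contact_map",
    "make_synthetic_pssm",
    "make_synthetic_dataset",
]

_HYDROPHOBIC = set("AILMVFWC")

# planted affinity: weights on (heavy-atom count, aromatic fraction,
# contact density, hydrophobic fraction), each min-max scaled to [0, 1]
_PLANT_WEIGHTS = np.array([1.0, 0.7, 0.8, 0.6])
_AFFINITY_RANGE = (5.0, 11.0)


def make_synthetic_contact_map(
    length: int,
    band_width: int = 2,
    p_long: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ContactMap:
    """Banded contact-probability matrix.

    Pairs within ``|i - j| <= band_width`` get probabilities in
    [0.8, 1.0]; each longer-range pair independently becomes a contact
    with probability ``p_long`` (probability drawn from [0.6, 1.0]); all
    remaining entries lie in [0, 0.4).  The matrix is symmetric, so the
    0.5 threshold recovers exactly the band plus the sampled long-range
    contacts.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if band_width < 0 or not (0.0 <= p_long <= 1.0):
        raise ValueError("band_width must be >= 0 and p_long in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = rng.uniform(0.0, 0.4, size=(length, length))
    idx = np.arange(length)
    near = np.abs(idx[:, None] - idx[None, :]) <= band_width
    band_vals = rng.uniform(0.8, 1.0, size=(length, length))
    probs = np.where(near, band_vals, probs)
    long_pick = rng.random((length, length)) < p_long
    long_vals = rng.uniform(0.6, 1.0, size=(length, length))
    probs = np.where(~near & long_pick, long_vals, probs)
    upper = np.triu(probs)
    sym = upper + np.triu(probs, k=1).T
    return ContactMap(sym)


def make_synthetic_pssm(
    length: int,
    concentration: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> PSSM:
    """PSSM with rows drawn from a symmetric Dirichlet over the 21 classes.

    Small concentrations give peaked (conserved-position-like) rows; as
    the concentration grows the rows flatten toward uniform 1/21.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(np.full(len(RESIDUES), concentration), size=length)
    return PSSM(rows)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = RESIDUES[:20]
    return "".join(letters[i] for i in rng.integers(0, 20, size=length))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo < 1e-12:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def make_synthetic_dataset(
    out_dir,
    n_drugs: int = 10,
    n_proteins: int = 5,
    protein_len_range: tuple[int, int] = (30, 60),
    noise_sd: float = 0.3,
    band_width: int = 2,
    p_long: float = 0.05,
    pssm_concentration: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
) -> AffinityDataset:
    """Generate and materialize a synthetic benchmark directory.

    The affinity of pair (drug i, protein j) is the planted score
    ``w . (heavy atoms, aromatic fraction, contact density, hydrophobic
    fraction)`` (each statistic min-max scaled over the generated
    entities) rescaled to pKd range [5, 11], plus N(0, noise_sd) noise.
    With ``noise_sd = 0`` the affinities are an exact deterministic
    function of the entity statistics.  The same seed always produces a
    byte-identical directory tree.
    """
    if n_drugs < 1 or n_proteins < 1:
        raise ValueError("n_drugs and n_proteins must be positive")
    if n_drugs > len(DRUG_SMILES):
        raise ValueError(
            f"n_drugs={n_drugs} exceeds the packaged library of {len(DRUG_SMILES)} SMILES"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    lo, hi = protein_len_range
    if lo < 1 or hi < lo:
        raise ValueError("protein_len_range must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- entities -----------------------------------------------------------
    smiles = [DRUG_SMILES[i] for i in rng.choice(len(DRUG_SMILES), n_drugs, replace=False)]
    ligands = {f"D{i:03d}": smi for i, smi in enumerate(smiles)}

    sequences: dict[str, str] = {}
    cmaps: dict[str, ContactMap] = {}
    pssms: dict[str, PSSM] = {}
    for j in range(n_proteins):
        pid = f"P{j:03d}"
        length = int(rng.integers(lo, hi + 1))
        sequences[pid] = _random_sequence(rng, length)
        cmaps[pid] = make_synthetic_contact_map(length, band_width, p_long, rng)
        pssms[pid] = make_synthetic_pssm(length, pssm_concentration, rng)

    # --- planted affinities -------------------------------------------------
    heavy = np.array([build_molecule_graph(s).n_nodes for s in smiles], dtype=float)
    arom = np.array(
        [build_molecule_graph(s).node_features[:, -1].mean() for s in smiles]
    )
    density = np.array(
        [
            (threshold_contact_map(cmaps[pid]).sum() - len(sequences[pid]))
            / max(len(sequences[pid]) ** 2 - len(sequences[pid]), 1)
            for pid in sequences
        ]
    )
    hydro = np.array(
        [
            sum(aa in _HYDROPHOBIC for aa in sequences[pid]) / len(sequences[pid])
            for pid in sequences
        ]
    )
    drug_stats = np.stack([_minmax(heavy), _minmax(arom)], axis=1)  # (n_drugs, 2)
    prot_stats = np.stack([_minmax(density), _minmax(hydro)], axis=1)  # (n_proteins, 2)
    score = (
        drug_stats @ _PLANT_WEIGHTS[:2]
    )[:, None] + (prot_stats @ _PLANT_WEIGHTS[2:])[None, :]
    lo_a, hi_a = _AFFINITY_RANGE
    span = score.max() - score.min()
    if span < 1e-12:
        affinity = np.full_like(score, 0.5 * (lo_a + hi_a))
    else:
        affinity = lo_a + (hi_a - lo_a) * (score - score.min()) / span
    if noise_sd > 0:
        affinity = affinity + rng.normal(0.0, noise_sd, size=affinity.shape)

    # --- materialize --------------------------------------------------------
    with open(out_dir / "ligands.json", "w") as fh:
        json.dump(ligands, fh, indent=2)
        fh.write("\n")
    with open(out_dir / "proteins.json", "w") as fh:
        json.dump(sequences, fh, indent=2)
        fh.write("\n")
    np.savetxt(out_dir / "affinity.txt", affinity, fmt="%.6f")
    for pid in sequences:
        write_matrix_file(out_dir / f"{pid}.cmap", cmaps[pid].probabilities)
        write_matrix_file(out_dir / f"{pid}.pssm", pssms[pid].scores, fmt="%.8f")

    n_records = n_drugs * n_proteins
    order = rng.permutation(n_records)
    fold_dir = out_dir / "folds"
    fold_dir.mkdir(exist_ok=True)
    for k, chunk in enumerate(np.array_split(order, n_folds)):
        with open(fold_dir / f"fold_{k}.json", "w") as fh:
            json.dump([int(i) for i in chunk], fh)
            fh.write("\n")

    return read_benchmark(out_dir)
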