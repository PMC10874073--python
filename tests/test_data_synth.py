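"""Benchmark I/O and the synthetic generator: round trips, determinism,
contact-map structure, planted-affinity behaviour."""

import filecmp
import json

import numpy as np
import pytest

import glcndta as g
from glcndta.data import read_benchmark
from glcndta.synthetic import DRUG_SMILES


class TestSyntheticContactMap:
    def test_band_one_thresholds_to_tridiagonal(self):
        cmap = g.make_synthetic_contact_map(8, band_width=1, p_long=0.0, seed=3)
        adj = g.threshold_contact_map(cmap)
        expected = np.tri(8, k=1) * np.tri(8, k=1).T  # |i-j| <= 1 band
        np.testing.assert_array_equal(adj, expected)

    def test_band_zero_no_long_range_is_identity(self):
        cmap = g.make_synthetic_contact_map(6, band_width=0, p_long=0.0, seed=1)
        np.testing.assert_array_equal(g.threshold_contact_map(cmap), np.eye(6))

    def test_symmetric_and_reproducible(self):
        a = g.make_synthetic_contact_map(12, seed=9).probabilities
        b = g.make_synthetic_contact_map(12, seed=9).probabilities
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, a.T)

    def test_long_range_contact_density_matches_rate(self):
        # Monte-Carlo: long-range (|i-j| > band) contact rate ~ p_long
        p_long, n, reps = 0.1, 40, 100
        idx = np.arange(n)
        far = np.abs(idx[:, None] - idx[None, :]) > 2
        np.fill_diagonal(far, False)
        rates = []
        for seed in range(reps):
            adj = g.threshold_contact_map(g.make_synthetic_contact_map(n, 2, p_long, seed))
            rates.append(adj[far].mean())
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(reps)
        assert abs(mean - p_long) < 3 * max(se, 1e-4)


class TestSyntheticPssm:
    def test_rows_sum_to_one(self):
        pssm = g.make_synthetic_pssm(15, seed=2)
        np.testing.assert_allclose(pssm.scores.sum(axis=1), 1.0, atol=1e-9)

    def test_reproducible(self):
        np.testing.assert_array_equal(
            g.make_synthetic_pssm(9, seed=4).scores, g.make_synthetic_pssm(9, seed=4).scores
        )

    def test_large_concentration_flattens_rows(self):
        peaked = g.make_synthetic_pssm(50, concentration=0.2, seed=0).scores
        flat = g.make_synthetic_pssm(50, concentration=500.0, seed=0).scores
        assert np.abs(flat - 1 / 21).max() < np.abs(peaked - 1 / 21).max()
        assert np.abs(flat - 1 / 21).max() < 0.02

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            g.make_synthetic_pssm(0)
        with pytest.raises(ValueError):
            g.make_synthetic_pssm(5, concentration=0.0)


class TestSyntheticDataset:
    def test_round_trips_with_full_record_grid(self, tmp_path):
        ds = g.make_synthetic_dataset(tmp_path / "b", n_drugs=4, n_proteins=3, seed=5)
        assert len(ds) == 12
        assert len(ds.ligands) == 4 and len(ds.proteins) == 3
        reread = read_benchmark(tmp_path / "b")
        assert [r.affinity for r in reread.records] == [r.affinity for r in ds.records]
        assert reread.folds == ds.folds
        assert sorted(i for f in reread.folds for i in f) == list(range(12))

    def test_same_seed_gives_byte_identical_trees(self, tmp_path):
        g.make_synthetic_dataset(tmp_path / "a", n_drugs=3, n_proteins=2, seed=8)
        g.make_synthetic_dataset(tmp_path / "b", n_drugs=3, n_proteins=2, seed=8)
        names = sorted(p.name for p in (tmp_path / "a").rglob("*") if p.is_file())
        assert names
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b",
            [str(p.relative_to(tmp_path / "a")) for p in (tmp_path / "a").rglob("*") if p.is_file()],
            shallow=False,
        )
        assert not mismatch and not errors

    def test_noise_free_affinity_is_deterministic_in_entities(self, tmp_path):
        a = g.make_synthetic_dataset(tmp_path / "a", n_drugs=5, n_proteins=3, noise_sd=0.0, seed=3)
        b = g.make_synthetic_dataset(tmp_path / "b", n_drugs=5, n_proteins=3, noise_sd=0.0, seed=3)
        np.testing.assert_array_equal(a.affinities, b.affinities)
        lo, hi = a.affinities.min(), a.affinities.max()
        assert 5.0 <= lo and hi <= 11.0  # Davis-like pKd range

    def test_drug_library_is_clean(self):
        assert len(DRUG_SMILES) >= 100
        sizes = [g.build_molecule_graph(s).n_nodes for s in DRUG_SMILES]
        assert min(sizes) >= 8 and max(sizes) <= 40

    def test_oversized_request_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            g.make_synthetic_dataset(tmp_path / "x", n_drugs=10_000)


class TestReadBenchmark:
    def test_nan_cells_are_dropped(self, tmp_path):
        d = tmp_path / "bench"
        d.mkdir()
        (d / "ligands.json").write_text(json.dumps({"d1": "CCO", "d2": "CCN"}))
        (d / "proteins.json").write_text(json.dumps({"p1": "ACD", "p2": "GAV"}))
        (d / "affinity.txt").write_text("5.0 nan\n6.0 7.0\n")
        for pid in ("p1", "p2"):
            np.savetxt(d / f"{pid}.cmap", np.eye(3))
            np.savetxt(d / f"{pid}.pssm", np.full((3, 21), 1 / 21))
        ds = read_benchmark(d)
        assert len(ds) == 3
        assert [(r.drug_id, r.protein_id) for r in ds.records] == [
            ("d1", "p1"), ("d2", "p1"), ("d2", "p2"),
        ]

    def test_kd_mode_applies_pkd_transform(self, tmp_path):
        d = tmp_path / "bench"
        d.mkdir()
        (d / "ligands.json").write_text(json.dumps({"d1": "CCO"}))
        (d / "proteins.json").write_text(json.dumps({"p1": "ACD"}))
        (d / "affinity.txt").write_text("10.0\n")
        np.savetxt(d / "p1.cmap", np.eye(3))
        np.savetxt(d / "p1.pssm", np.full((3, 21), 1 / 21))
        ds = read_benchmark(d, kd_to_pkd=True)
        assert ds.records[0].affinity == pytest.approx(8.0)

    def test_fold_files_must_partition_records(self, tmp_path):
        ds_dir = tmp_path / "bench"
        g.make_synthetic_dataset(ds_dir, n_drugs=2, n_proteins=2, n_folds=2, seed=0)
        # corrupt: drop an index from one fold
        fold0 = ds_dir / "folds" / "fold_0.json"
        idx = json.loads(fold0.read_text())
        fold0.write_text(json.dumps(idx[:-1]))
        with pytest.raises(ValueError, match="partition"):
            read_benchmark(ds_dir)

    def test_missing_files_are_named(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        with pytest.raises(FileNotFoundError, match="ligands.json"):
            read_benchmark(d)

    def test_ragged_matrix_rejected(self, tmp_path):
        d = tmp_path / "bench"
        d.mkdir()
        (d / "ligands.json").write_text(json.dumps({"d1": "CCO"}))
        (d / "proteins.json").write_text(json.dumps({"p1": "ACD"}))
        (d / "affinity.txt").write_text("1.0 2.0\n")
        np.savetxt(d / "p1.cmap", np.eye(3))
        np.savetxt(d / "p1.pssm", np.full((3, 21), 1 / 21))
        with pytest.raises(ValueError, match="affinity.txt"):
            read_benchmark(d)


class TestAlternateInputs:
    def test_fasta_accepted_in_place_of_protein_table(self, tmp_path):
        src = tmp_path / "src"
        g.make_synthetic_dataset(src, n_drugs=2, n_proteins=2, seed=1)
        seqs = json.loads((src / "proteins.json").read_text())
        (src / "proteins.json").unlink()
        with open(src / "proteins.fasta", "w") as fh:
            for pid, seq in seqs.items():
                fh.write(f">{pid}\n{seq}\n")
        ds = read_benchmark(src)
        assert {p: e.sequence for p, e in ds.proteins.items()} == seqs

    def test_smiles_file_reader_skips_blanks_and_comments(self, tmp_path):
        from glcndta.chem_graph import read_smiles_file

        path = tmp_path / "mols.smi"
        path.write_text("# library\nCCO ethanol\n\nc1ccccc1\n")
        assert read_smiles_file(path) == ["CCO", "c1ccccc1"]
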