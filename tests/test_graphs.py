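"""Molecular graph featurization and adjacency normalization."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from cdrlearn.exceptions import FeaturizationError, ValidationError
from cdrlearn.graphs import (
    N_ATOM_FEATURES,
    featurize_smiles,
    load_drug_library,
    normalize_adjacency,
)

# feature-block offsets in the 75-length layout
SYMBOL = slice(0, 44)
DEGREE = slice(44, 55)
VALENCE = slice(55, 62)
CHARGE = 62
RADICALS = 63
HYBRID = slice(64, 69)
AROMATIC = 69
TOTAL_H = slice(70, 75)


class TestFeaturizeSmiles:
    def test_methane_single_heavy_atom(self):
        g = featurize_smiles("C")
        assert g.n_atoms == 1
        assert g.atom_features.shape == (1, N_ATOM_FEATURES)
        np.testing.assert_array_equal(g.adjacency, [[0.0]])
        # carbon one-hot, 4 implicit hydrogens
        assert g.atom_features[0, SYMBOL][0] == 1.0
        assert g.atom_features[0, TOTAL_H][4] == 1.0

    def test_ethanol_topology_matches_rdkit(self):
        g = featurize_smiles("CCO")
        assert g.n_atoms == 3
        assert g.adjacency.sum() == 2 * 2  # two undirected bonds
        np.testing.assert_array_equal(g.adjacency.sum(axis=1), [1.0, 2.0, 1.0])
        ref = Chem.GetAdjacencyMatrix(Chem.MolFromSmiles("CCO"))
        np.testing.assert_array_equal(g.adjacency, ref.astype(float))

    def test_benzene_aromatic_ring(self):
        g = featurize_smiles("c1ccccc1")
        assert g.n_atoms == 6
        assert (g.atom_features[:, AROMATIC] == 1.0).all()
        np.testing.assert_array_equal(g.adjacency.sum(axis=1), np.full(6, 2.0))
        # aromatic carbons are SP2
        assert (g.atom_features[:, HYBRID][:, 1] == 1.0).all()

    def test_feature_vectors_binary_except_charge_and_radicals(self):
        for smiles in ("CCO", "c1ccccc1", "CC(=O)[O-]", "O=C(O)c1ccccc1O"):
            X = featurize_smiles(smiles).atom_features
            others = np.delete(X, [CHARGE, RADICALS], axis=1)
            assert np.isin(others, (0.0, 1.0)).all(), smiles

    def test_formal_charge_slot(self):
        X = featurize_smiles("CC(=O)[O-]").atom_features
        assert X[:, CHARGE].min() == -1.0

    def test_largest_fragment_kept_for_salts(self):
        salt = featurize_smiles("CC(=O)O.[Na+]")
        acid_frag = featurize_smiles("CC(=O)O")
        assert salt.n_atoms == acid_frag.n_atoms

    def test_unparseable_smiles_error_carries_string(self):
        with pytest.raises(FeaturizationError, match="xyz123"):
            featurize_smiles("xyz123((")

    def test_row_sums_match_rdkit_degree_for_library(self, smiles_library):
        for smiles in smiles_library[:20]:
            g = featurize_smiles(smiles)
            mol = Chem.MolFromSmiles(smiles)
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
            mol = max(frags, key=lambda f: f.GetNumAtoms())
            degrees = [a.GetDegree() for a in mol.GetAtoms()]
            np.testing.assert_array_equal(g.adjacency.sum(axis=1), degrees)


class TestNormalizeAdjacency:
    def test_single_node(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((1, 1))), [[1.0]], atol=1e-12)

    def test_two_node_edge(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), np.full((2, 2), 0.5), atol=1e-12)

    def test_triangle(self):
        A = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(normalize_adjacency(A), np.full((3, 3), 1.0 / 3.0), atol=1e-12)

    def test_matches_elementwise_formula_on_random_molecules(self, smiles_library):
        for smiles in smiles_library:
            A = featurize_smiles(smiles).adjacency
            a_hat = normalize_adjacency(A)
            A_tilde = A + np.eye(len(A))
            d = A_tilde.sum(axis=1)
            brute = np.array(
                [
                    [A_tilde[i, j] / np.sqrt(d[i] * d[j]) for j in range(len(A))]
                    for i in range(len(A))
                ]
            )
            np.testing.assert_allclose(a_hat, brute, atol=1e-12)
            assert np.abs(a_hat - a_hat.T).max() == 0.0
            # spectral radius of the normalized operator stays at/below 1
            assert np.abs(np.linalg.eigvalsh(a_hat)).max() <= 1.0 + 1e-6

    def test_permutation_equivariance(self, smiles_library):
        rng = np.random.default_rng(11)
        for smiles in smiles_library[:10]:
            A = featurize_smiles(smiles).adjacency
            perm = rng.permutation(len(A))
            P = np.eye(len(A))[perm]
            lhs = normalize_adjacency(P @ A @ P.T)
            rhs = P @ normalize_adjacency(A) @ P.T
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValidationError, match="diagonal"):
            normalize_adjacency(np.eye(2))


class TestLoadDrugLibrary:
    def _write(self, tmp_path, rows):
        p = tmp_path / "drugs.csv"
        pd.DataFrame(rows, columns=["drug_id", "smiles"]).to_csv(p, index=False)
        return p

    def test_valid_file(self, tmp_path):
        p = self._write(tmp_path, [("a", "CCO"), ("b", "c1ccccc1"), ("c", "CC(=O)O")])
        graphs = load_drug_library(p)
        assert [g.drug_id for g in graphs] == ["a", "b", "c"]

    def test_duplicate_id_rejected_with_row(self, tmp_path):
        p = self._write(tmp_path, [("a", "CCO"), ("a", "CC")])
        with pytest.raises(ValidationError, match="row 3"):
            load_drug_library(p)

    def test_invalid_smiles_aborts_with_row(self, tmp_path):
        p = self._write(tmp_path, [("a", "CCO"), ("b", "not_smiles((")])
        with pytest.raises(FeaturizationError, match="row 3"):
            load_drug_library(p)

    def test_empty_file_returns_empty_list(self, tmp_path):
        p = self._write(tmp_path, [])
        assert load_drug_library(p) == []
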