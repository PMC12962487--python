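"""Featurization: layouts, descriptor definitions, scaling, graph building."""

import numpy as np
import pytest
from rdkit import Chem

from graphscreen.curation import curate
from graphscreen.datasplit import randomize_smiles
from graphscreen.featurize import (
    ATOM_FEATURE_DIM,
    ATOM_FEATURE_LAYOUT,
    BOND_FEATURE_DIM,
    BOND_FEATURE_LAYOUT,
    DESCRIPTOR_DIM,
    DESCRIPTOR_NAMES,
    ElementOutOfVocabulary,
    apply_scaler,
    build_graph,
    compute_descriptors,
    featurize_atom,
    featurize_bond,
    fit_scaler,
    load_dataset,
    save_dataset,
)


def _block(vector, layout, name):
    start = 0
    for block_name, size in layout:
        if block_name == name:
            return vector[start : start + size]
        start += size
    raise KeyError(name)


class TestAtomFeatures:
    def test_layout_sums_to_78(self):
        assert sum(s for _, s in ATOM_FEATURE_LAYOUT) == ATOM_FEATURE_DIM == 78

    def test_benzene_carbon(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        v = featurize_atom(mol.GetAtomWithIdx(0))
        assert v.shape == (78,)
        assert _block(v, ATOM_FEATURE_LAYOUT, "aromatic")[0] == 1
        assert _block(v, ATOM_FEATURE_LAYOUT, "in_ring")[0] == 1
        assert _block(v, ATOM_FEATURE_LAYOUT, "ring_size")[6 - 3] == 1
        assert _block(v, ATOM_FEATURE_LAYOUT, "hybridization")[2] == 1  # SP2
        assert _block(v, ATOM_FEATURE_LAYOUT, "degree")[2] == 1
        assert _block(v, ATOM_FEATURE_LAYOUT, "total_h")[1] == 1

    def test_ethanol_oxygen(self):
        mol = Chem.MolFromSmiles("CCO")
        v = featurize_atom(mol.GetAtomWithIdx(2))
        assert _block(v, ATOM_FEATURE_LAYOUT, "element")[2] == 1  # O
        assert _block(v, ATOM_FEATURE_LAYOUT, "degree")[1] == 1
        assert _block(v, ATOM_FEATURE_LAYOUT, "total_h")[1] == 1
        assert _block(v, ATOM_FEATURE_LAYOUT, "aromatic")[0] == 0
        assert _block(v, ATOM_FEATURE_LAYOUT, "in_ring")[0] == 0
        assert _block(v, ATOM_FEATURE_LAYOUT, "mass")[0] == pytest.approx(0.16, abs=0.001)

    def test_one_hot_blocks_exactly_one_nonzero(self, small_library):
        one_hot_blocks = (
            "element",
            "degree",
            "formal_charge",
            "chirality",
            "total_h",
            "hybridization",
            "implicit_valence",
            "explicit_valence",
            "radical_electrons",
        )
        records, _ = small_library
        compounds, _ = curate(records)
        for c in compounds[:30]:
            mol = Chem.MolFromSmiles(c.canonical_smiles)
            for atom in mol.GetAtoms():
                v = featurize_atom(atom)
                assert np.all(np.isfinite(v))
                for name in one_hot_blocks:
                    block = _block(v, ATOM_FEATURE_LAYOUT, name)
                    assert np.count_nonzero(block) == 1, name

    def test_out_of_vocabulary_element(self):
        mol = Chem.MolFromSmiles("C[Se]C")
        with pytest.raises(ElementOutOfVocabulary):
            featurize_atom(mol.GetAtomWithIdx(1))


class TestBondFeatures:
    def test_layout_sums_to_12(self):
        assert sum(s for _, s in BOND_FEATURE_LAYOUT) == BOND_FEATURE_DIM == 12

    def test_benzene_ring_bond(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        v = featurize_bond(mol.GetBondWithIdx(0))
        assert v.shape == (12,)
        assert _block(v, BOND_FEATURE_LAYOUT, "bond_type")[3] == 1  # aromatic
        assert _block(v, BOND_FEATURE_LAYOUT, "conjugated")[0] == 1
        assert _block(v, BOND_FEATURE_LAYOUT, "in_ring")[0] == 1
        assert _block(v, BOND_FEATURE_LAYOUT, "stereo")[0] == 1  # none

    def test_ethane_single_bond(self):
        v = featurize_bond(Chem.MolFromSmiles("CC").GetBondWithIdx(0))
        assert _block(v, BOND_FEATURE_LAYOUT, "bond_type")[0] == 1
        assert _block(v, BOND_FEATURE_LAYOUT, "conjugated")[0] == 0
        assert _block(v, BOND_FEATURE_LAYOUT, "in_ring")[0] == 0

    def test_trans_butene_stereo(self):
        mol = Chem.MolFromSmiles("C/C=C/C")
        double = next(
            b for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
        )
        v = featurize_bond(double)
        assert _block(v, BOND_FEATURE_LAYOUT, "bond_type")[1] == 1
        assert _block(v, BOND_FEATURE_LAYOUT, "stereo")[3] == 1  # E


class TestDescriptors:
    def test_length_and_frozen_ordering(self):
        assert len(DESCRIPTOR_NAMES) == DESCRIPTOR_DIM == 50
        assert DESCRIPTOR_NAMES[:6] == (
            "MolWt",
            "MolLogP",
            "NumHDonors",
            "NumHAcceptors",
            "TPSA",
            "NumRotatableBonds",
        )

    def test_ethanol(self):
        d = compute_descriptors(Chem.MolFromSmiles("CCO"))
        assert d.shape == (50,)
        names = dict(zip(DESCRIPTOR_NAMES, d))
        assert names["NumHDonors"] == 1
        assert names["NumHAcceptors"] == 1
        assert names["NumRotatableBonds"] == 0  # terminal hydroxyl rotor excluded

    def test_benzene(self):
        names = dict(zip(DESCRIPTOR_NAMES, compute_descriptors(Chem.MolFromSmiles("c1ccccc1"))))
        assert names["NumAromaticRings"] == 1
        assert names["TPSA"] == 0.0


class TestScaler:
    def test_constant_column_warns_and_zeroes(self):
        x = np.ones((5, 50))
        with pytest.warns(UserWarning, match="constant"):
            scaler = fit_scaler(x)
        scaled = apply_scaler(scaler, x)
        assert np.allclose(scaled, 0.0)
        assert np.all(scaler.std == 1.0)

    def test_single_molecule_scales_to_zero(self):
        x = np.random.default_rng(0).normal(size=(1, 50))
        with pytest.warns(UserWarning):
            scaler = fit_scaler(x)
        assert np.allclose(apply_scaler(scaler, x[0]), 0.0)

    def test_gaussian_recovery(self, rng):
        mu = rng.normal(size=50) * 10
        sd = rng.uniform(0.5, 3.0, size=50)
        x = rng.normal(mu, sd, size=(4000, 50))
        scaler = fit_scaler(x)
        assert np.allclose(scaler.mean, mu, atol=0.2)
        assert np.allclose(scaler.std, sd, rtol=0.1)
        z = apply_scaler(scaler, x)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_empty_fit_raises(self):
        with pytest.raises(ValueError):
            fit_scaler(np.zeros((0, 50)))


class TestBuildGraph:
    def test_methane_edgeless_graph_is_legal(self):
        g = build_graph("C")
        assert g.n_atoms == 1 and g.edges.shape == (2, 0)
        assert g.atom_features.shape == (1, 78)

    def test_ethanol_directed_edges(self):
        g = build_graph("CCO")
        assert g.n_atoms == 3
        assert g.edges.shape == (2, 4)  # 2 bonds x 2 directions
        assert g.bond_features.shape == (4, 12)

    def test_benzene_symmetric_ring(self):
        g = build_graph("c1ccccc1")
        assert g.n_atoms == 6 and g.edges.shape == (2, 12)
        assert np.all(g.bond_features == g.bond_features[0])

    def test_directed_edge_pairs_share_features(self):
        g = build_graph("CC(=O)Nc1ccc(O)cc1")  # paracetamol
        pair_of = {}
        for k in range(g.edges.shape[1]):
            key = tuple(sorted((g.edges[0, k], g.edges[1, k])))
            pair_of.setdefault(key, []).append(g.bond_features[k])
        for feats in pair_of.values():
            assert len(feats) == 2
            assert np.array_equal(feats[0], feats[1])

    def test_content_invariant_to_smiles_spelling(self):
        smiles = "CC(=O)Nc1ccc(O)cc1"
        g_ref = build_graph(smiles)
        for variant in randomize_smiles(smiles, max_variants=3, seed=3):
            g = build_graph(variant)
            assert g.n_atoms == g_ref.n_atoms
            # node multiset
            ref_rows = sorted(map(tuple, g_ref.atom_features))
            rows = sorted(map(tuple, g.atom_features))
            assert rows == ref_rows
            assert np.allclose(g.descriptors_raw, g_ref.descriptors_raw)

    def test_label_carried(self):
        assert build_graph("CCO", label=1).label == 1

    def test_out_of_vocabulary_propagates(self):
        with pytest.raises(ElementOutOfVocabulary):
            build_graph("C[Se]C")


class TestDatasetRoundTrip:
    def test_save_load_identity(self, tmp_path):
        graphs = [build_graph(s, label=y) for s, y in
                  [("CCO", 1), ("c1ccccc1", 0), ("C", None), ("CC(=O)O", 1)]]
        scaler = fit_scaler(np.random.default_rng(0).normal(size=(10, 50)))
        path = tmp_path / "data.npz"
        save_dataset(path, graphs, scaler)
        back, back_scaler = load_dataset(path)
        assert len(back) == len(graphs)
        for a, b in zip(graphs, back):
            assert a.n_atoms == b.n_atoms
            assert np.array_equal(a.atom_features, b.atom_features)
            assert np.array_equal(a.edges, b.edges)
            assert np.array_equal(a.bond_features, b.bond_features)
            assert np.array_equal(a.descriptors_raw, b.descriptors_raw)
            assert a.label == b.label
            assert a.canonical_smiles == b.canonical_smiles
        assert np.array_equal(back_scaler.mean, scaler.mean)
        assert np.array_equal(back_scaler.std, scaler.std)
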