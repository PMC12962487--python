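"""Molecular graph featurization: 78-dim atoms, 12-dim bonds, 50 descriptors.

Atoms are heavy atoms only (hydrogens enter via the total-H one-hot). The
atom vector is a fixed sequence of one-hot blocks plus flags; every one-hot
block has exactly one nonzero entry (out-of-range categorical values clip
into the last in-range bucket, elements outside the 9-element vocabulary
reject the whole molecule). Bonds are emitted as two directed edges with
identical 12-dim feature vectors.

The 50 global descriptors are a frozen, ordered list of standard RDKit 2D
descriptors, the first six being MW, LogP, HBD, HBA, TPSA and rotatable
bonds. Scaling is z-score, fit on the training split only; descriptors that
are constant on the training set get unit standard deviation (and scale to
zero) with a warning.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.QED import qed

from .molio import StandardizedMolecule

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

ATOM_FEATURE_DIM = 78
BOND_FEATURE_DIM = 12
DESCRIPTOR_DIM = 50

#: Ordered (name, size) blocks of the atom feature vector; sizes sum to 78.
ATOM_FEATURE_LAYOUT = (
    ("element", 9),
    ("degree", 11),  # 0..10
    ("formal_charge", 7),  # -3..+3 clipped
    ("chirality", 4),  # unspecified, CW, CCW, other
    ("total_h", 11),  # 0..10
    ("hybridization", 8),  # S, SP, SP2, SP3, SP3D, SP3D2, other, unspecified
    ("aromatic", 1),
    ("mass", 1),  # mass / 100
    ("in_ring", 1),
    ("ring_size", 6),  # flags for ring sizes 3..8
    ("implicit_valence", 7),  # 0..6
    ("explicit_valence", 7),  # 0..6
    ("radical_electrons", 5),  # 0..4
)

BOND_FEATURE_LAYOUT = (
    ("bond_type", 4),  # single, double, triple, aromatic
    ("conjugated", 1),
    ("in_ring", 1),
    ("stereo", 6),  # none, any, Z, E, cis, trans
)

assert sum(s for _, s in ATOM_FEATURE_LAYOUT) == ATOM_FEATURE_DIM
assert sum(s for _, s in BOND_FEATURE_LAYOUT) == BOND_FEATURE_DIM


class ElementOutOfVocabulary(ValueError):
    """Molecule contains an element outside the 9-element vocabulary."""


@dataclass
class MolecularGraph:
    n_atoms: int
    atom_features: np.ndarray  # (N, 78)
    edges: np.ndarray  # (2, 2E) directed pairs, both directions per bond
    bond_features: np.ndarray  # (2E, 12)
    descriptors_raw: np.ndarray  # (50,)
    label: int | None = None
    canonical_smiles: str = ""


def _one_hot(value: int, size: int, offset: int = 0) -> np.ndarray:
    v = np.zeros(size)
    v[int(np.clip(value - offset, 0, size - 1))] = 1.0
    return v


_HYBRIDIZATION = {
    Chem.HybridizationType.S: 0,
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
    Chem.HybridizationType.SP3D: 4,
    Chem.HybridizationType.SP3D2: 5,
    # anything else -> "other" (6); UNSPECIFIED -> 7
}

_CHIRALITY = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
    # anything else -> "other" (3)
}

_BOND_TYPE = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

_BOND_STEREO = {
    Chem.BondStereo.STEREONONE: 0,
    Chem.BondStereo.STEREOANY: 1,
    Chem.BondStereo.STEREOZ: 2,
    Chem.BondStereo.STEREOE: 3,
    Chem.BondStereo.STEREOCIS: 4,
    Chem.BondStereo.STEREOTRANS: 5,
}


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """78-dim feature vector for one atom in its molecular context."""
    symbol = atom.GetSymbol()
    if symbol not in ELEMENTS:
        raise ElementOutOfVocabulary(symbol)
    mol = atom.GetOwningMol()
    ring_info = mol.GetRingInfo()
    hyb = atom.GetHybridization()
    if hyb == Chem.HybridizationType.UNSPECIFIED:
        hyb_idx = 7
    else:
        hyb_idx = _HYBRIDIZATION.get(hyb, 6)
    chirality_idx = _CHIRALITY.get(atom.GetChiralTag(), 3)
    parts = [
        _one_hot(ELEMENTS.index(symbol), 9),
        _one_hot(atom.GetDegree(), 11),
        _one_hot(atom.GetFormalCharge(), 7, offset=-3),
        _one_hot(chirality_idx, 4),
        _one_hot(atom.GetTotalNumHs(), 11),
        _one_hot(hyb_idx, 8),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
        np.array([atom.GetMass() / 100.0]),
        np.array([1.0 if atom.IsInRing() else 0.0]),
        np.array(
            [
                1.0 if ring_info.IsAtomInRingOfSize(atom.GetIdx(), size) else 0.0
                for size in range(3, 9)
            ]
        ),
        _one_hot(atom.GetImplicitValence(), 7),
        _one_hot(atom.GetExplicitValence(), 7),
        _one_hot(atom.GetNumRadicalElectrons(), 5),
    ]
    return np.concatenate(parts)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """12-dim feature vector for one bond (direction-independent)."""
    parts = [
        _one_hot(_BOND_TYPE.get(bond.GetBondType(), 0), 4),
        np.array([1.0 if bond.GetIsConjugated() else 0.0]),
        np.array([1.0 if bond.IsInRing() else 0.0]),
        _one_hot(_BOND_STEREO.get(bond.GetStereo(), 0), 6),
    ]
    return np.concatenate(parts)


# ------------------------------------------------------------------ descriptors


def _num_halogens(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("F", "Cl", "Br", "I"))


#: Frozen ordered list of the 50 global 2D descriptors.
DESCRIPTOR_FUNCS: tuple[tuple[str, object], ...] = (
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Descriptors.MolLogP),
    ("NumHDonors", Descriptors.NumHDonors),
    ("NumHAcceptors", Descriptors.NumHAcceptors),
    ("TPSA", Descriptors.TPSA),
    ("NumRotatableBonds", Descriptors.NumRotatableBonds),
    ("RingCount", Descriptors.RingCount),
    ("NumAromaticRings", Descriptors.NumAromaticRings),
    ("NumAliphaticRings", Descriptors.NumAliphaticRings),
    ("NumSaturatedRings", Descriptors.NumSaturatedRings),
    ("NumAromaticHeterocycles", Descriptors.NumAromaticHeterocycles),
    ("NumAliphaticHeterocycles", Descriptors.NumAliphaticHeterocycles),
    ("NumSaturatedHeterocycles", Descriptors.NumSaturatedHeterocycles),
    ("NumAromaticCarbocycles", Descriptors.NumAromaticCarbocycles),
    ("NumAliphaticCarbocycles", Descriptors.NumAliphaticCarbocycles),
    ("NumSaturatedCarbocycles", Descriptors.NumSaturatedCarbocycles),
    ("FractionCSP3", Descriptors.FractionCSP3),
    ("HeavyAtomCount", Descriptors.HeavyAtomCount),
    ("NumHeteroatoms", Descriptors.NumHeteroatoms),
    ("NOCount", Descriptors.NOCount),
    ("NHOHCount", Descriptors.NHOHCount),
    ("NumRadicalElectrons", Descriptors.NumRadicalElectrons),
    ("MolMR", Descriptors.MolMR),
    ("LabuteASA", Descriptors.LabuteASA),
    ("BalabanJ", Descriptors.BalabanJ),
    ("BertzCT", Descriptors.BertzCT),
    ("Chi0", Descriptors.Chi0),
    ("Chi1", Descriptors.Chi1),
    ("Chi0n", Descriptors.Chi0n),
    ("Chi1n", Descriptors.Chi1n),
    ("Chi2n", Descriptors.Chi2n),
    ("Chi3n", Descriptors.Chi3n),
    ("Chi4n", Descriptors.Chi4n),
    ("Chi0v", Descriptors.Chi0v),
    ("Chi1v", Descriptors.Chi1v),
    ("Chi2v", Descriptors.Chi2v),
    ("Chi3v", Descriptors.Chi3v),
    ("Chi4v", Descriptors.Chi4v),
    ("Kappa1", Descriptors.Kappa1),
    ("Kappa2", Descriptors.Kappa2),
    ("Kappa3", Descriptors.Kappa3),
    ("HallKierAlpha", Descriptors.HallKierAlpha),
    ("ExactMolWt", Descriptors.ExactMolWt),
    ("HeavyAtomMolWt", Descriptors.HeavyAtomMolWt),
    ("NumValenceElectrons", Descriptors.NumValenceElectrons),
    ("QED", qed),
    ("NumAmideBonds", rdMolDescriptors.CalcNumAmideBonds),
    ("NumSpiroAtoms", rdMolDescriptors.CalcNumSpiroAtoms),
    ("NumBridgeheadAtoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
    ("NumHalogenAtoms", _num_halogens),
)

DESCRIPTOR_NAMES = tuple(name for name, _ in DESCRIPTOR_FUNCS)
assert len(DESCRIPTOR_FUNCS) == DESCRIPTOR_DIM


def compute_descriptors(mol: Chem.Mol) -> np.ndarray:
    """50 global 2D descriptors in the frozen DESCRIPTOR_NAMES order."""
    values = np.empty(DESCRIPTOR_DIM)
    for i, (name, fn) in enumerate(DESCRIPTOR_FUNCS):
        try:
            values[i] = float(fn(mol))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"descriptor {name} failed: {exc}") from exc
    if not np.all(np.isfinite(values)):
        bad = DESCRIPTOR_NAMES[int(np.argmax(~np.isfinite(values)))]
        raise ValueError(f"descriptor {bad} returned a non-finite value")
    return values


@dataclass
class DescriptorScaler:
    """Per-descriptor z-scoring, fitted on the training split only."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.mean) / self.std


def fit_scaler(training_descriptors: np.ndarray) -> DescriptorScaler:
    x = np.asarray(training_descriptors, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("fit_scaler requires a non-empty (n, 50) matrix")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} descriptor(s) constant on the training set; "
            "std set to 1",
            stacklevel=2,
        )
        std = np.where(constant, 1.0, std)
    return DescriptorScaler(mean=mean, std=std)


def apply_scaler(scaler: DescriptorScaler, raw: np.ndarray) -> np.ndarray:
    return scaler.transform(raw)


# ------------------------------------------------------------------ graphs


def build_graph(
    mol_or_std: Chem.Mol | StandardizedMolecule | str,
    label: int | None = None,
) -> MolecularGraph:
    """MolecularGraph for one standardized molecule.

    Bonds become two directed edges with duplicated features; an edgeless
    single-atom graph is legal. Raises ElementOutOfVocabulary for molecules
    outside the element vocabulary.
    """
    if isinstance(mol_or_std, StandardizedMolecule):
        mol = Chem.MolFromSmiles(mol_or_std.canonical_smiles)
    elif isinstance(mol_or_std, str):
        mol = Chem.MolFromSmiles(mol_or_std)
    else:
        mol = mol_or_std
    if mol is None:
        raise ValueError("invalid molecule")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("empty molecule")
    atom_features = np.stack([featurize_atom(a) for a in mol.GetAtoms()])
    src: list[int] = []
    dst: list[int] = []
    feats: list[np.ndarray] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        src.extend((i, j))
        dst.extend((j, i))
        feats.extend((f, f))
    edges = np.array([src, dst], dtype=np.intp).reshape(2, -1)
    bond_features = (
        np.stack(feats) if feats else np.zeros((0, BOND_FEATURE_DIM))
    )
    return MolecularGraph(
        n_atoms=n,
        atom_features=atom_features,
        edges=edges,
        bond_features=bond_features,
        descriptors_raw=compute_descriptors(mol),
        label=label,
        canonical_smiles=Chem.MolToSmiles(mol),
    )


# ------------------------------------------------------------------ on-disk


def save_dataset(
    path: str | os.PathLike,
    graphs: list[MolecularGraph],
    scaler: DescriptorScaler | None = None,
) -> None:
    """Serialize featurized graphs (+ optional scaler sidecar) to one .npz."""
    atom_ptr = np.cumsum([0] + [g.n_atoms for g in graphs])
    edge_ptr = np.cumsum([0] + [g.edges.shape[1] for g in graphs])
    payload = {
        "atom_ptr": atom_ptr,
        "edge_ptr": edge_ptr,
        "atom_features": (
            np.concatenate([g.atom_features for g in graphs])
            if graphs
            else np.zeros((0, ATOM_FEATURE_DIM))
        ),
        "edges": (
            np.concatenate([g.edges for g in graphs], axis=1)
            if graphs
            else np.zeros((2, 0), dtype=np.intp)
        ),
        "bond_features": (
            np.concatenate([g.bond_features for g in graphs])
            if graphs
            else np.zeros((0, BOND_FEATURE_DIM))
        ),
        "descriptors": (
            np.stack([g.descriptors_raw for g in graphs])
            if graphs
            else np.zeros((0, DESCRIPTOR_DIM))
        ),
        "labels": np.array(
            [-1 if g.label is None else int(g.label) for g in graphs], dtype=np.int64
        ),
        "smiles": np.array([g.canonical_smiles for g in graphs], dtype=str),
    }
    if scaler is not None:
        payload["scaler_mean"] = scaler.mean
        payload["scaler_std"] = scaler.std
    with open(path, "wb") as fh:  # keep the exact path (no forced .npz suffix)
        np.savez(fh, **payload)


def load_dataset(
    path: str | os.PathLike,
) -> tuple[list[MolecularGraph], DescriptorScaler | None]:
    with np.load(path) as data:
        atom_ptr = data["atom_ptr"]
        edge_ptr = data["edge_ptr"]
        graphs: list[MolecularGraph] = []
        labels = data["labels"]
        smiles = data["smiles"]
        for k in range(len(atom_ptr) - 1):
            a0, a1 = atom_ptr[k], atom_ptr[k + 1]
            e0, e1 = edge_ptr[k], edge_ptr[k + 1]
            graphs.append(
                MolecularGraph(
                    n_atoms=int(a1 - a0),
                    atom_features=data["atom_features"][a0:a1],
                    edges=(
                        data["edges"][:, e0:e1].astype(np.intp)
                        if e1 > e0
                        else np.zeros((2, 0), dtype=np.intp)
                    ),
                    bond_features=data["bond_features"][e0:e1],
                    descriptors_raw=data["descriptors"][k],
                    label=None if labels[k] < 0 else int(labels[k]),
                    canonical_smiles=str(smiles[k]),
                )
            )
        scaler = None
        if "scaler_mean" in data:
            scaler = DescriptorScaler(mean=data["scaler_mean"], std=data["scaler_std"])
    return graphs, scaler
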