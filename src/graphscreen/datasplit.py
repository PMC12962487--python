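"""Scaffold splitting, similarity auditing, sampling weights, augmentation.

Bemis-Murcko scaffold splitting assigns whole scaffold groups to splits so
no scaffold crosses a split boundary: groups are ordered by descending size
(ties by scaffold string) and greedily fill train, then validation, then
test to their target counts. Acyclic molecules (empty scaffold) form a
single group. The train/test separation is audited with per-test-compound
maximum Tanimoto similarity on ECFP4 fingerprints (circular, radius 2 —
the "4" is the diameter — 2048 bits).

SMILES randomization re-spells a molecule with a permuted atom order; every
variant canonicalizes back to the source structure, so augmented training
copies vary the input serialization without touching the label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

ECFP4_RADIUS = 2
ECFP4_NBITS = 2048

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(
    radius=ECFP4_RADIUS, fpSize=ECFP4_NBITS
)


@dataclass
class SplitAssignment:
    train: list[int]
    valid: list[int]
    test: list[int]
    fractions: tuple[float, float, float]
    seed: int
    scaffolds: list[str] = field(default_factory=list)  # per-compound

    def as_dict(self) -> dict:
        return {
            "train": list(map(int, self.train)),
            "valid": list(map(int, self.valid)),
            "test": list(map(int, self.test)),
            "fractions": list(self.fractions),
            "seed": self.seed,
            "scaffolds": self.scaffolds,
        }


@dataclass
class SimilarityAudit:
    max_similarity: np.ndarray  # per test compound
    median: float
    p95: float


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def scaffold_split(
    compounds,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 42,
) -> SplitAssignment:
    """Greedy deterministic scaffold split.

    `compounds` is a sequence of LabeledCompound (scaffold fields are filled
    in place) or of SMILES strings. Groups sorted by (-size, scaffold) fill
    train, then valid, then test to target counts; the seed is recorded for
    provenance (assignment itself is deterministic).
    """
    if len(compounds) == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")

    scaffolds: list[str] = []
    for c in compounds:
        smiles = c if isinstance(c, str) else c.canonical_smiles
        scaf = murcko_scaffold(smiles)
        scaffolds.append(scaf)
        if not isinstance(c, str):
            c.scaffold = scaf

    groups: dict[str, list[int]] = {}
    for idx, scaf in enumerate(scaffolds):
        groups.setdefault(scaf, []).append(idx)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    n = len(scaffolds)
    targets = [fractions[0] * n, fractions[1] * n, fractions[2] * n]
    splits: tuple[list[int], ...] = ([], [], [])
    for _, members in ordered:
        # greedy: the split with the largest remaining deficit takes the
        # whole group; ties resolve train > valid > test
        deficits = [targets[k] - len(splits[k]) for k in range(3)]
        splits[int(np.argmax(deficits))].extend(members)
    train, valid, test = splits
    for name, split in (("train", train), ("valid", valid), ("test", test)):
        if not split:
            warnings.warn(f"{name} split is empty", stacklevel=2)
    return SplitAssignment(
        train=train,
        valid=valid,
        test=test,
        fractions=tuple(fractions),
        seed=seed,
        scaffolds=scaffolds,
    )


# ------------------------------------------------------------------ similarity


def ecfp4(smiles: str) -> np.ndarray:
    """2048-bit ECFP4 fingerprint as a 0/1 numpy vector."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    fp = _MORGAN.GetFingerprint(mol)
    arr = np.zeros(ECFP4_NBITS, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B| on equal-length bit vectors; 0 when both empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def similarity_audit(
    train_smiles: list[str], test_smiles: list[str]
) -> SimilarityAudit:
    """Per-test-compound max Tanimoto to any train compound (ECFP4)."""
    if not train_smiles or not test_smiles:
        raise ValueError("similarity_audit requires non-empty train and test sets")
    train_fps = []
    for s in train_smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES {s!r}")
        train_fps.append(_MORGAN.GetFingerprint(mol))
    maxima = np.empty(len(test_smiles))
    for i, s in enumerate(test_smiles):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES {s!r}")
        sims = DataStructs.BulkTanimotoSimilarity(
            _MORGAN.GetFingerprint(mol), train_fps
        )
        maxima[i] = max(sims)
    # linear interpolation between order statistics
    return SimilarityAudit(
        max_similarity=maxima,
        median=float(np.percentile(maxima, 50)),
        p95=float(np.percentile(maxima, 95)),
    )


# ---------------------------------------------------------------- augmentation


def randomize_smiles(
    smiles_or_mol, max_variants: int = 3, seed: int = 42
) -> list[str]:
    """Up to `max_variants` distinct non-canonical spellings of one molecule.

    Every variant re-canonicalizes to the source canonical SMILES. Small
    molecules may admit fewer distinct spellings than requested.
    """
    if max_variants < 0:
        raise ValueError("max_variants must be >= 0")
    if max_variants == 0:
        return []
    mol = (
        Chem.MolFromSmiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    if mol is None:
        raise ValueError("invalid molecule")
    canonical = Chem.MolToSmiles(mol)
    rng = np.random.default_rng(seed)
    variants: list[str] = []
    seen = {canonical}
    n = mol.GetNumAtoms()
    for _ in range(20 + 10 * max_variants):
        perm = rng.permutation(n).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        spelled = Chem.MolToSmiles(shuffled, canonical=False)
        if spelled not in seen:
            seen.add(spelled)
            variants.append(spelled)
            if len(variants) == max_variants:
                break
    return variants


def augment_training_set(
    compounds,
    ratio: float = 0.3,
    max_variants: int = 3,
    seed: int = 42,
) -> list[tuple[str, int]]:
    """Static augmentation pass over the training split only.

    Each molecule is included once as its canonical SMILES; with probability
    `ratio` it additionally contributes up to `max_variants` randomized
    spellings sharing its label. Returns (smiles, label) pairs.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, int]] = []
    for c in compounds:
        out.append((c.canonical_smiles, c.label))
        if ratio > 0 and rng.random() < ratio:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            for variant in randomize_smiles(
                c.canonical_smiles, max_variants=max_variants, seed=sub_seed
            ):
                out.append((variant, c.label))
    return out


# ------------------------------------------------------------------- sampling


def sampler_weights(labels) -> np.ndarray:
    """Class-inverse weights for sampling with replacement (expected 1:1)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label vector")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("sampler_weights requires both classes present")
    counts = {1: n_pos, 0: n_neg}
    return np.array([1.0 / counts[int(y)] for y in labels])
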