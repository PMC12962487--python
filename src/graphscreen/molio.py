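"""Molecule standardization and tabular bioactivity I/O.

Standardization turns an arbitrary SMILES into the canonical form of its
largest organic fragment with charges neutralized where chemically valid
(carboxylates back to acids, protonated amines back to free bases;
quaternary ammonium centers keep their charge). Stereochemistry is
preserved — the featurizer consumes it downstream.

The tabular layer reads delimited activity tables (compound_id, smiles,
endpoint, value, unit, target_id), dropping and counting malformed rows,
and round-trips labeled compound sets through CSV.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")  # RDKit warnings are reported via Rejections

ENDPOINTS = ("IC50", "Ki", "Kd")
UNITS = ("nM", "uM", "M")

_UNIT_ALIASES = {
    "nm": "nM",
    "um": "uM",
    "µm": "uM",  # micro sign
    "μm": "uM",  # greek mu
    "m": "M",
}
_ENDPOINT_ALIASES = {"ic50": "IC50", "ki": "Ki", "kd": "Kd"}

REQUIRED_COLUMNS = ("compound_id", "smiles", "endpoint", "value", "unit", "target_id")


@dataclass(frozen=True)
class RawBioactivityRecord:
    """One measured endpoint for one compound."""

    compound_id: str
    smiles: str
    endpoint: str  # IC50 | Ki | Kd
    value: float  # > 0
    unit: str  # nM | uM | M
    target_id: str

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unsupported endpoint {self.endpoint!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unsupported unit {self.unit!r}")
        if not self.smiles:
            raise ValueError("empty SMILES")
        if not self.value > 0:
            raise ValueError("activity value must be positive")


@dataclass(frozen=True)
class StandardizedMolecule:
    canonical_smiles: str
    n_heavy_atoms: int
    was_desalted: bool = False
    was_neutralized: bool = False


@dataclass(frozen=True)
class Rejection:
    input_smiles: str
    reason: str  # unparseable | empty_after_desalting | standardization_failure


@dataclass
class ParseReport:
    """Row bookkeeping for read_records."""

    n_rows: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def summary(self) -> str:
        lines = [f"rows={self.n_rows} kept={self.n_kept}"]
        for reason, n in sorted(self.dropped.items()):
            lines.append(f"dropped[{reason}]={n}")
        return "\n".join(lines)


_UNCHARGER = rdMolStandardize.Uncharger()


def _largest_organic_fragment(mol: Chem.Mol) -> tuple[Chem.Mol | None, bool]:
    """Keep the carbon-containing fragment with the most heavy atoms.

    Ties break on canonical-SMILES lexicographic order. Returns
    (fragment, was_desalted); fragment is None when no organic piece remains.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        frag = frags[0]
        has_c = any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())
        return (frag, False) if has_c else (None, False)
    organic = []
    for frag in frags:
        if any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
            organic.append(frag)
    if not organic:
        return None, True
    keyed = sorted(
        organic,
        key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )
    return keyed[0], True


def standardize(smiles: str) -> StandardizedMolecule | Rejection:
    """Canonicalize a SMILES: desalt, neutralize, emit toolkit-canonical form.

    Idempotent: re-standardizing the output string reproduces it exactly.
    """
    if not smiles or not isinstance(smiles, str):
        return Rejection(input_smiles=str(smiles), reason="unparseable")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return Rejection(input_smiles=smiles, reason="unparseable")
    frag, was_desalted = _largest_organic_fragment(mol)
    if frag is None:
        return Rejection(input_smiles=smiles, reason="empty_after_desalting")
    try:
        Chem.SanitizeMol(frag)
        charges_before = [a.GetFormalCharge() for a in frag.GetAtoms()]
        neutral = _UNCHARGER.uncharge(frag)
        charges_after = [a.GetFormalCharge() for a in neutral.GetAtoms()]
        was_neutralized = charges_before != charges_after
        canonical = Chem.MolToSmiles(neutral)
        if not canonical:
            return Rejection(input_smiles=smiles, reason="standardization_failure")
    except Exception:
        return Rejection(input_smiles=smiles, reason="standardization_failure")
    return StandardizedMolecule(
        canonical_smiles=canonical,
        n_heavy_atoms=neutral.GetNumHeavyAtoms(),
        was_desalted=was_desalted,
        was_neutralized=was_neutralized,
    )


def mol_from_standardized(std: StandardizedMolecule) -> Chem.Mol:
    mol = Chem.MolFromSmiles(std.canonical_smiles)
    if mol is None:  # cannot happen for output of standardize()
        raise ValueError(f"invalid canonical SMILES {std.canonical_smiles!r}")
    return mol


# ----------------------------------------------------------------- tabular I/O


def read_records(
    path: str | os.PathLike, dialect: str = "csv"
) -> tuple[list[RawBioactivityRecord], ParseReport]:
    """Read an activity table; malformed rows are dropped and counted."""
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    sep = "," if dialect == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    report = ParseReport(n_rows=len(df))
    records: list[RawBioactivityRecord] = []
    for row in df.itertuples(index=False):
        smiles = row.smiles.strip()
        if not smiles:
            report.dropped["empty_smiles"] += 1
            continue
        endpoint = _ENDPOINT_ALIASES.get(row.endpoint.strip().lower())
        if endpoint is None:
            report.dropped["unsupported_endpoint"] += 1
            continue
        unit = _UNIT_ALIASES.get(row.unit.strip().lower())
        if unit is None:
            report.dropped["unsupported_unit"] += 1
            continue
        try:
            value = float(row.value)
        except ValueError:
            report.dropped["non_numeric_value"] += 1
            continue
        if not value > 0:
            report.dropped["non_positive_value"] += 1
            continue
        records.append(
            RawBioactivityRecord(
                compound_id=row.compound_id,
                smiles=smiles,
                endpoint=endpoint,
                value=value,
                unit=unit,
                target_id=row.target_id,
            )
        )
    report.n_kept = len(records)
    return records, report


LABELED_COLUMNS = ("canonical_smiles", "ic50_um", "label", "scaffold")


def write_labeled(path: str | os.PathLike, compounds) -> None:
    """Write LabeledCompound rows to CSV; round-trips exactly via read_labeled."""
    df = pd.DataFrame(
        {
            "canonical_smiles": [c.canonical_smiles for c in compounds],
            "ic50_um": [repr(float(c.ic50_um)) for c in compounds],
            "label": [int(c.label) for c in compounds],
            "scaffold": [c.scaffold for c in compounds],
        },
        columns=list(LABELED_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_labeled(path: str | os.PathLike):
    from .curation import LabeledCompound  # deferred: avoids import cycle

    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LABELED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    return [
        LabeledCompound(
            canonical_smiles=row.canonical_smiles,
            ic50_um=float(row.ic50_um),
            label=int(row.label),
            scaffold=row.scaffold,
        )
        for row in df.itertuples(index=False)
    ]


def read_smi(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a .smi screening library: one 'SMILES [id]' per line."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"MOL{i:06d}"
            out.append((smiles, mol_id))
    return out


def read_sdf(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read structures from an SDF (read-only); returns (smiles, id) pairs."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    out: list[tuple[str, str]] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"MOL{i:06d}"
        out.append((Chem.MolToSmiles(mol), name or f"MOL{i:06d}"))
    return out
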