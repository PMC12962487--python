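"""Bioactivity curation: raw records -> deduplicated, labeled, drug-like set.

Pipeline order: standardize -> unit conversion -> threshold labeling (drop
the 10-30 uM gray zone) -> per-molecule deduplication keeping the most
potent value -> druggability filter (molecular-weight window + reactive
substructure blacklist). Every removal is counted in a CurationReport.

Label semantics: IC50 <= 10 uM positive (closed), > 30 uM negative (open),
(10, 30] excluded to reduce label noise near the decision boundary. Ki/Kd
endpoints are treated as IC50-equivalent after unit conversion unless
``ic50_only`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors

from .molio import RawBioactivityRecord, Rejection, standardize

#: Default reactive/undesirable substructure blacklist (SMARTS).
REACTIVE_SMARTS: dict[str, str] = {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "michael_acceptor_enone": "[CX3]=[CX3][CX3]=[OX1]",
    "epoxide": "C1OC1",
    "isocyanate": "[NX2]=C=O",
    "azide": "[NX1]~[NX2]~[NX2,NX1]",
    "activated_alkyl_halide": "[Cl,Br,I][CX4][#7,#8,#16]",
    "peroxide": "[OX2][OX2]",
    "nitroso": "[#6][NX2]=[OX1]",
    "anhydride": "[CX3](=O)[OX2][CX3](=O)",
}


@dataclass(frozen=True)
class CurationConfig:
    pos_threshold_um: float = 10.0
    neg_threshold_um: float = 30.0
    mw_min_da: float = 150.0
    mw_max_da: float = 800.0
    reactive_smarts: dict = field(default_factory=lambda: dict(REACTIVE_SMARTS))
    ic50_only: bool = False  # restrict to IC50 endpoints (drop Ki/Kd)
    ignore_stereo_in_dedup: bool = False

    def __post_init__(self):
        if not (0 < self.pos_threshold_um < self.neg_threshold_um):
            raise ValueError("need 0 < pos_threshold_um < neg_threshold_um")
        if not self.mw_min_da < self.mw_max_da:
            raise ValueError("need mw_min_da < mw_max_da")


@dataclass
class LabeledCompound:
    canonical_smiles: str
    ic50_um: float
    label: int  # 1 active, 0 inactive
    scaffold: str = ""  # filled by datasplit


@dataclass
class CurationReport:
    """Survivor counts after each stage (non-increasing along the pipeline);
    ``excluded_gray_zone`` counts gray-zone drops, ``removals`` all drops."""

    parsed: int = 0
    standardized: int = 0
    unit_converted: int = 0
    labeled: int = 0
    excluded_gray_zone: int = 0
    deduplicated: int = 0
    filtered_mw: int = 0
    filtered_reactive: int = 0
    final: int = 0
    removals: dict = field(default_factory=dict)

    def summary(self) -> str:
        stages = [
            "parsed",
            "standardized",
            "unit_converted",
            "labeled",
            "deduplicated",
            "filtered_mw",
            "filtered_reactive",
            "final",
        ]
        lines = [f"{s}={getattr(self, s)}" for s in stages]
        lines.append(f"excluded_gray_zone={self.excluded_gray_zone}")
        for reason, n in sorted(self.removals.items()):
            lines.append(f"removed[{reason}]={n}")
        return "\n".join(lines)


_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "M": 1e6}


def to_micromolar(value: float, unit: str) -> float:
    """Convert an activity value to micromolar."""
    if unit not in _UNIT_TO_UM:
        raise ValueError(f"unsupported unit {unit!r}")
    if not value > 0:
        raise ValueError("activity value must be positive")
    return value * _UNIT_TO_UM[unit]


def assign_label(ic50_um: float, config: CurationConfig = CurationConfig()) -> str:
    """Threshold labeling: 'positive', 'negative', or 'excluded' (gray zone)."""
    if not ic50_um > 0:
        raise ValueError("ic50_um must be positive")
    if ic50_um <= config.pos_threshold_um:
        return "positive"
    if ic50_um > config.neg_threshold_um:
        return "negative"
    return "excluded"


def deduplicate(records: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """One record per canonical SMILES, keeping the minimum (most potent)
    IC50; output sorted by canonical SMILES."""
    best: dict[str, float] = {}
    for smiles, ic50 in records:
        if smiles not in best or ic50 < best[smiles]:
            best[smiles] = ic50
    return sorted(best.items())


def druggability_filter(
    std_mol, config: CurationConfig = CurationConfig()
) -> tuple[bool, str | None]:
    """Molecular-weight window + reactive-group blacklist on the desalted
    parent. Returns (keep, reason); reason in {mw_low, mw_high, reactive}."""
    mol = Chem.MolFromSmiles(std_mol.canonical_smiles)
    if mol is None:
        return False, "unparseable"
    mw = Descriptors.MolWt(mol)  # average atomic masses
    if mw < config.mw_min_da:
        return False, "mw_low"
    if mw > config.mw_max_da:
        return False, "mw_high"
    for name, smarts in config.reactive_smarts.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.HasSubstructMatch(patt):
            return False, "reactive"
    return True, None


def curate(
    records: list[RawBioactivityRecord],
    config: CurationConfig = CurationConfig(),
) -> tuple[list[LabeledCompound], CurationReport]:
    """Run the full curation pipeline; failures become report counts."""
    report = CurationReport(parsed=len(records))
    removals: dict[str, int] = {}

    def drop(reason: str, n: int = 1) -> None:
        removals[reason] = removals.get(reason, 0) + n

    # stage 1: standardize
    standardized: list[tuple[str, RawBioactivityRecord]] = []
    smiles_cache: dict[str, object] = {}
    for rec in records:
        if config.ic50_only and rec.endpoint != "IC50":
            drop("endpoint_not_ic50")
            continue
        if rec.smiles not in smiles_cache:
            smiles_cache[rec.smiles] = standardize(rec.smiles)
        std = smiles_cache[rec.smiles]
        if isinstance(std, Rejection):
            drop(f"standardize_{std.reason}")
            continue
        standardized.append((std.canonical_smiles, rec))
    report.standardized = len(standardized)

    # stage 2: unit conversion (units validated at parse; conversion is total)
    converted = [(smi, to_micromolar(rec.value, rec.unit)) for smi, rec in standardized]
    report.unit_converted = len(converted)

    # stage 3: threshold labeling, dropping the gray zone
    labeled_records: list[tuple[str, float]] = []
    for smi, ic50 in converted:
        if assign_label(ic50, config) == "excluded":
            report.excluded_gray_zone += 1
        else:
            labeled_records.append((smi, ic50))
    drop("gray_zone", report.excluded_gray_zone) if report.excluded_gray_zone else None
    report.labeled = len(labeled_records)

    # stage 4: deduplicate on canonical SMILES keeping the most potent value
    if config.ignore_stereo_in_dedup:
        keyed = []
        for smi, ic50 in labeled_records:
            mol = Chem.MolFromSmiles(smi)
            Chem.RemoveStereochemistry(mol)
            keyed.append((Chem.MolToSmiles(mol), ic50))
        deduped = deduplicate(keyed)
    else:
        deduped = deduplicate(labeled_records)
    drop("duplicate", report.labeled - len(deduped))
    report.deduplicated = len(deduped)

    # stage 5: druggability filter
    from .molio import StandardizedMolecule

    survivors_mw: list[tuple[str, float]] = []
    survivors: list[tuple[str, float]] = []
    for smi, ic50 in deduped:
        std = StandardizedMolecule(canonical_smiles=smi, n_heavy_atoms=1)
        keep, reason = druggability_filter(std, config)
        if reason in ("mw_low", "mw_high"):
            drop(reason)
            continue
        survivors_mw.append((smi, ic50))
        if not keep:
            drop(reason)
            continue
        survivors.append((smi, ic50))
    report.filtered_mw = len(survivors_mw)
    report.filtered_reactive = len(survivors)
    report.final = len(survivors)
    report.removals = removals

    compounds = [
        LabeledCompound(
            canonical_smiles=smi,
            ic50_um=ic50,
            label=1 if assign_label(ic50, config) == "positive" else 0,
        )
        for smi, ic50 in survivors
    ]
    return compounds, report
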