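"""Seeded generator of ChEMBL-like bioactivity records with a planted
structure-activity rule.

Molecules are assembled from a small fragment grammar: a ring scaffold with
two substitution sites, an "A" substituent (either a sulfonamide-bearing
active motif or an inert decoy) and a "B" bulk substituent. Activity is
attached to the motif — a *substituent*, not a scaffold — so Bemis-Murcko
scaffold splitting cannot separate the signal, which makes held-out
recovery a test of learning rather than memorization.

Potencies are log-normal in log10 space: motif-bearing molecules draw IC50
around a 1 uM median, others around 100 uM (sd 0.5 log10 units), so the two
distributions overlap the 10-30 uM gray zone and the exclusion rule is
exercised. Draws crossing the opposite label boundary are resampled so
that, at zero label noise, curation recovers the motif labeling exactly
(minus gray-zone exclusions). ChEMBL-style messiness is injected on top:
counterion fragments (salt forms), duplicate measurements, mixed
nM/uM/M units and IC50/Ki/Kd endpoint types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molio import RawBioactivityRecord

#: Ring scaffolds with two substitution sites. Distinct Bemis-Murcko cores
#: (substituents are acyclic, so each template maps to exactly one core).
SCAFFOLDS: tuple[str, ...] = (
    "c1cc({A})ccc1{B}",  # benzene
    "c1cc({A})cnc1{B}",  # pyridine
    "c1nc({A})cnc1{B}",  # pyrazine
    "c1sc({A})nc1{B}",  # thiazole
    "c1cc({A})c(s1){B}",  # thiophene
    "c1cc({A})c(o1){B}",  # furan
    "C1CC({A})CCC1{B}",  # cyclohexane
    "C1CC({A})CC1{B}",  # cyclopentane
    "C1CN({A})CCC1{B}",  # piperidine (N-substituted)
    "C1CN({A})CCN1{B}",  # piperazine
    "C1CC({A})OCC1{B}",  # tetrahydropyran
    "O=C1CC({A})CCN1{B}",  # piperidin-2-one
    "O1CCN({A})CC1{B}",  # morpholine
    "c1ccc2cc({A})c({B})cc2c1",  # naphthalene
    "c1ccc2nc({A})c({B})cc2c1",  # quinoline
    "c1ccc2c(c1)cc({A})n2{B}",  # indole (N-substituted)
    "c1ccc2c(c1)oc({A})c2{B}",  # benzofuran
    "c1ccc2c(c1)sc({A})c2{B}",  # benzothiophene
    "C1Cc2ccccc2C({A})C1{B}",  # tetralin
    "C1({B})COc2ccc({A})cc2O1",  # benzodioxane
    "c1cc2c(cc1{A})CCC2{B}",  # indane
    "c1cc({B})c2c(c1)nc({A})o2",  # benzoxazole
)

#: Motif-bearing A-substituents (sulfonamide SMARTS matches all of them).
MOTIF_SUBSTITUENTS: tuple[str, ...] = (
    "S(=O)(=O)N",
    "S(=O)(=O)NC",
    "CS(=O)(=O)N",
    "S(=O)(=O)N(C)C",
)

#: Inert A-substituents (sulfur-free; never match the motif).
DECOY_SUBSTITUENTS: tuple[str, ...] = (
    "C(=O)NC",
    "C(=O)OC",
    "C(=O)N(C)C",
    "CC(C)O",
    "N(C)C",
    "CC#N",
    "C(F)(F)F",
    "OCC(F)F",
    "CCOC",
    "C(C)(C)C",
)

#: Bulk B-substituents sized to keep MW inside the 150-800 Da window.
BULK_SUBSTITUENTS: tuple[str, ...] = (
    "CCCC",
    "CCCCC",
    "OCCC",
    "OCCOC",
    "CC(C)CC",
    "N(CC)CC",
    "CCCOC",
    "CCN(C)C",
    "OCC(C)C",
    "CCCC(C)C",
)

ACTIVE_MOTIF_SMARTS = "S(=O)(=O)N"

SALT_FRAGMENTS: tuple[str, ...] = ("Cl", "[Na+].[Cl-]", "OS(=O)(=O)O")


@dataclass(frozen=True)
class SyntheticConfig:
    n_molecules: int = 600
    active_fraction: float = 0.3  # planted motif prevalence (class imbalance)
    active_motif: str = ACTIVE_MOTIF_SMARTS
    ic50_active_median_um: float = 1.0
    ic50_inactive_median_um: float = 100.0
    ic50_log10_sd: float = 0.5
    label_noise: float = 0.0  # probability of swapping the generating dist.
    duplicate_rate: float = 0.1
    salt_rate: float = 0.1
    unit_mix: dict = field(
        default_factory=lambda: {"nM": 0.6, "uM": 0.35, "M": 0.05}
    )
    endpoint_mix: dict = field(
        default_factory=lambda: {"IC50": 0.7, "Ki": 0.2, "Kd": 0.1}
    )
    seed: int = 7

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must lie in [0, 1)")
        for name in ("duplicate_rate", "salt_rate", "active_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (
            self.ic50_active_median_um
            < 10.0
            < 30.0
            < self.ic50_inactive_median_um
        ):
            raise ValueError("IC50 medians must straddle the 10/30 uM thresholds")


@dataclass
class TruthRecord:
    compound_id: str
    base_smiles: str
    has_motif: bool
    generating_distribution: str  # active | inactive


def _assemble(scaffold: str, sub_a: str, sub_b: str) -> str:
    return scaffold.replace("{A}", sub_a).replace("{B}", sub_b)


def enumerate_base_molecules() -> tuple[list[str], list[str]]:
    """All grammar products as (motif-bearing, decoy) SMILES lists.

    Every product parses; this is asserted by the test suite along with the
    MW window and scaffold diversity.
    """
    actives, decoys = [], []
    for scaffold in SCAFFOLDS:
        for sub_b in BULK_SUBSTITUENTS:
            for sub_a in MOTIF_SUBSTITUENTS:
                actives.append(_assemble(scaffold, sub_a, sub_b))
            for sub_a in DECOY_SUBSTITUENTS:
                decoys.append(_assemble(scaffold, sub_a, sub_b))
    return actives, decoys


def has_motif(smiles: str, motif_smarts: str = ACTIVE_MOTIF_SMARTS) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    return mol.HasSubstructMatch(Chem.MolFromSmarts(motif_smarts))


def _draw_ic50(
    rng: np.random.Generator, config: SyntheticConfig, active: bool
) -> float:
    """Log10-normal IC50 (uM), resampled away from the opposite label region."""
    median = (
        config.ic50_active_median_um if active else config.ic50_inactive_median_um
    )
    for _ in range(1000):
        value = 10.0 ** rng.normal(np.log10(median), config.ic50_log10_sd)
        if active and value <= 30.0:
            return value
        if not active and value > 10.0:
            return value
    raise RuntimeError("IC50 resampling failed")  # pragma: no cover


def _pick(rng: np.random.Generator, mix: dict) -> str:
    keys = list(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _record(
    rng: np.random.Generator,
    config: SyntheticConfig,
    compound_id: str,
    smiles: str,
    ic50_um: float,
) -> RawBioactivityRecord:
    unit = _pick(rng, config.unit_mix)
    value = ic50_um * {"nM": 1e3, "uM": 1.0, "M": 1e-6}[unit]
    return RawBioactivityRecord(
        compound_id=compound_id,
        smiles=smiles,
        endpoint=_pick(rng, config.endpoint_mix),
        value=value,
        unit=unit,
        target_id="SYNTARG-1",
    )


def generate_library(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[RawBioactivityRecord], list[TruthRecord]]:
    """Deterministic synthetic bioactivity library + ground-truth table."""
    rng = np.random.default_rng(config.seed)
    actives_pool, decoys_pool = enumerate_base_molecules()
    n_active = int(round(config.active_fraction * config.n_molecules))
    n_decoy = config.n_molecules - n_active
    if n_active > len(actives_pool) or n_decoy > len(decoys_pool):
        raise ValueError(
            f"n_molecules={config.n_molecules} exceeds grammar capacity "
            f"({len(actives_pool)} motif / {len(decoys_pool)} decoy products)"
        )
    chosen_active = rng.permutation(len(actives_pool))[:n_active]
    chosen_decoy = rng.permutation(len(decoys_pool))[:n_decoy]
    base = [(actives_pool[i], True) for i in chosen_active] + [
        (decoys_pool[i], False) for i in chosen_decoy
    ]
    order = rng.permutation(len(base))

    records: list[RawBioactivityRecord] = []
    truth: list[TruthRecord] = []
    for k, idx in enumerate(order):
        smiles, motif = base[idx]
        compound_id = f"SYN{k:05d}"
        draw_active = motif
        if config.label_noise > 0 and rng.random() < config.label_noise:
            draw_active = not draw_active
        ic50 = _draw_ic50(rng, config, draw_active)
        reported = smiles
        if rng.random() < config.salt_rate:
            reported = smiles + "." + SALT_FRAGMENTS[rng.choice(len(SALT_FRAGMENTS))]
        records.append(_record(rng, config, compound_id, reported, ic50))
        if rng.random() < config.duplicate_rate:
            dup_ic50 = _draw_ic50(rng, config, draw_active)
            records.append(_record(rng, config, compound_id, reported, dup_ic50))
        truth.append(
            TruthRecord(
                compound_id=compound_id,
                base_smiles=smiles,
                has_motif=motif,
                generating_distribution="active" if draw_active else "inactive",
            )
        )
    return records, truth


def recovery_experiment(
    synth_config: SyntheticConfig = SyntheticConfig(),
    model_config=None,
    train_config=None,
    fractions: tuple = (0.8, 0.1, 0.1),
    max_epochs: int | None = 40,
    augment: bool = True,
    verbose: bool = False,
):
    """End-to-end planted-signal recovery: generate -> curate -> split ->
    featurize -> fit -> evaluate on the scaffold-held-out test set.

    Returns (metrics, model, details); details carries the split, test
    probabilities/labels/SMILES and the curation report for oracle checks.
    """
    from .curation import CurationConfig, curate
    from .datasplit import augment_training_set, scaffold_split
    from .featurize import build_graph, fit_scaler
    from .gnn import GraphScreenModel, ModelConfig
    from .train import TrainConfig, fit

    if model_config is None:
        model_config = ModelConfig(hidden_dim=64, n_heads=4, n_layers=2)
    if train_config is None:
        train_config = TrainConfig()

    records, truth = generate_library(synth_config)
    compounds, report = curate(records, CurationConfig())
    split = scaffold_split(compounds, fractions, seed=train_config.seed)

    train_cpds = [compounds[i] for i in split.train]
    valid_cpds = [compounds[i] for i in split.valid]
    test_cpds = [compounds[i] for i in split.test]

    if augment:
        train_items = augment_training_set(
            train_cpds,
            ratio=train_config.augmentation_ratio,
            max_variants=train_config.max_smiles_variants,
            seed=train_config.seed,
        )
    else:
        train_items = [(c.canonical_smiles, c.label) for c in train_cpds]

    train_graphs = [build_graph(s, label=y) for s, y in train_items]
    valid_graphs = [
        build_graph(c.canonical_smiles, label=c.label) for c in valid_cpds
    ]
    test_graphs = [build_graph(c.canonical_smiles, label=c.label) for c in test_cpds]

    scaler = fit_scaler(np.stack([g.descriptors_raw for g in train_graphs]))
    model = GraphScreenModel(model_config, seed=train_config.seed)
    model, history = fit(
        model,
        train_graphs,
        valid_graphs,
        train_config,
        scaler=scaler,
        max_epochs=max_epochs,
        verbose=verbose,
    )

    from .evaluate import classification_metrics

    test_probs = model.predict_proba(test_graphs, scaler)
    test_labels = np.array([c.label for c in test_cpds], dtype=int)
    metrics = classification_metrics(test_probs, test_labels)
    details = {
        "split": split,
        "history": history,
        "curation_report": report,
        "truth": truth,
        "scaler": scaler,
        "test_probs": test_probs,
        "test_labels": test_labels,
        "test_smiles": [c.canonical_smiles for c in test_cpds],
    }
    return metrics, model, details
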