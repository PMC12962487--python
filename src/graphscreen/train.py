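"""Training loop: smoothed BCE, balanced sampling, warm restarts, early stop.

The loss is binary cross-entropy against label-smoothed targets
y~ = y(1 - eps) + eps/2 (eps = 0.1 gives the 0.05/0.95 soft labels).
Mini-batches are drawn with replacement under class-inverse weights so the
expected class ratio is 1:1. Gradients are averaged over
``accumulation_steps`` consecutive mini-batches (effective batch =
batch_size x accumulation_steps), clipped to a global L2 norm, and applied
with AdamW. The learning rate follows cosine annealing with warm restarts
(T0, T_mult), stepped per epoch. Early stopping watches validation AUC and
reverts to the best recorded weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datasplit import sampler_weights
from .evaluate import roc_auc
from .featurize import DescriptorScaler, MolecularGraph
from .gnn import GraphBatch, GraphScreenModel


@dataclass(frozen=True)
class ScheduleConfig:
    T0: int = 10
    T_mult: int = 2
    eta_min: float = 1e-7
    eta_max: float = 1e-3  # base learning rate

    def __post_init__(self):
        if not self.eta_min < self.eta_max:
            raise ValueError("need eta_min < eta_max")


@dataclass(frozen=True)
class TrainConfig:
    epsilon: float = 0.1  # label smoothing
    batch_size: int = 64
    accumulation_steps: int = 2
    clip_norm: float = 3.0
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    patience_epochs: int = 20
    min_delta_auc: float = 0.001
    augmentation_ratio: float = 0.3
    max_smiles_variants: int = 3
    weight_decay: float = 1e-5
    pos_class_weight: float | None = None  # optional extra loss weight
    seed: int = 42
    max_epochs: int = 200

    def __post_init__(self):
        if not 0 <= self.epsilon < 1:
            raise ValueError("need 0 <= epsilon < 1")
        if self.accumulation_steps < 1:
            raise ValueError("accumulation_steps must be >= 1")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def best_auc(self) -> float:
        return self.epochs[self.best_epoch]["val_auc"] if self.epochs else float("nan")


def smooth_target(y: float | np.ndarray, epsilon: float) -> np.ndarray:
    """y~ = y(1 - eps) + eps/2; eps=0.1 maps {0,1} -> {0.05, 0.95}."""
    return np.asarray(y, dtype=float) * (1.0 - epsilon) + epsilon / 2.0


def smoothed_bce(
    p: nn.Tensor | np.ndarray,
    y: np.ndarray,
    epsilon: float = 0.1,
    pos_weight: float | None = None,
) -> nn.Tensor:
    """Mean label-smoothed binary cross-entropy.

    Probabilities are clamped into [1e-7, 1 - 1e-7] before the logarithms.
    """
    if not isinstance(p, nn.Tensor):
        p = nn.Tensor(p)
    y = np.asarray(y, dtype=float).reshape(p.data.shape)
    y_soft = smooth_target(y, epsilon)
    p = p.clip(1e-7, 1.0 - 1e-7)
    per_sample = -(y_soft * p.log() + (1.0 - y_soft) * (1.0 - p).log())
    if pos_weight is not None:
        w = np.where(y == 1, pos_weight, 1.0)
        per_sample = per_sample * w
        return per_sample.sum() * (1.0 / w.sum())
    return per_sample.mean()


def effective_batch(config: TrainConfig) -> int:
    return config.batch_size * config.accumulation_steps


def lr_at(epoch: float, schedule: ScheduleConfig = ScheduleConfig()) -> float:
    """Cosine annealing with warm restarts; restarts at 10, 30, 70, ... epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    t = float(epoch)
    T_k = float(schedule.T0)
    while t >= T_k:
        t -= T_k
        T_k *= schedule.T_mult
    return schedule.eta_min + 0.5 * (schedule.eta_max - schedule.eta_min) * (
        1.0 + math.cos(math.pi * t / T_k)
    )


def restart_boundaries(schedule: ScheduleConfig, n: int = 3) -> list[int]:
    """Cumulative epochs at which the schedule restarts (10, 30, 70, ...)."""
    out, total, T_k = [], 0, schedule.T0
    for _ in range(n):
        total += T_k
        out.append(total)
        T_k *= schedule.T_mult
    return out


def fit(
    model: GraphScreenModel,
    train_graphs: list[MolecularGraph],
    valid_graphs: list[MolecularGraph],
    config: TrainConfig = TrainConfig(),
    scaler: DescriptorScaler | None = None,
    max_epochs: int | None = None,
    verbose: bool = False,
) -> tuple[GraphScreenModel, TrainHistory]:
    """Train in place; returns (model restored to best-AUC weights, history).

    Augmentation (randomized-SMILES copies) is applied upstream of this
    function, on the training split only; here every element of
    ``train_graphs`` is treated as one sample. Deterministic for a fixed
    config seed and dataset.
    """
    if not train_graphs or not valid_graphs:
        raise ValueError("train and validation splits must be non-empty")
    labels = np.array([g.label for g in train_graphs], dtype=float)
    weights = sampler_weights(labels)  # raises on single-class input
    probs = weights / weights.sum()
    val_labels = np.array([g.label for g in valid_graphs], dtype=int)

    rng = np.random.default_rng(config.seed)
    from .evaluate import classification_metrics

    opt = nn.AdamW(
        model.parameters(),
        lr=config.schedule.eta_max,
        weight_decay=config.weight_decay,
    )
    history = TrainHistory()
    best_auc = -np.inf
    best_state = model.get_state()
    best_epoch = -1
    epochs_since_improvement = 0
    n = len(train_graphs)
    n_epochs = config.max_epochs if max_epochs is None else max_epochs

    for epoch in range(n_epochs):
        lr = lr_at(epoch, config.schedule)
        order = rng.choice(n, size=n, replace=True, p=probs)
        batch_starts = range(0, n, config.batch_size)
        epoch_loss = 0.0
        n_batches = 0
        accumulated = 0
        opt.zero_grad()
        for start in batch_starts:
            idx = order[start : start + config.batch_size]
            batch = GraphBatch.from_graphs([train_graphs[i] for i in idx], scaler)
            p = model.forward(batch, train=True, rng=rng)
            loss = smoothed_bce(
                p, batch.labels, config.epsilon, config.pos_class_weight
            ) * (1.0 / config.accumulation_steps)
            loss.backward()
            epoch_loss += float(loss.data) * config.accumulation_steps
            n_batches += 1
            accumulated += 1
            if accumulated == config.accumulation_steps:
                nn.clip_global_norm(model.parameters(), config.clip_norm)
                opt.step(lr)
                opt.zero_grad()
                accumulated = 0
        if accumulated:  # trailing partial accumulation window
            nn.clip_global_norm(model.parameters(), config.clip_norm)
            opt.step(lr)
            opt.zero_grad()

        val_probs = model.predict_proba(valid_graphs, scaler)
        val_auc = roc_auc(val_probs, val_labels)
        metrics = classification_metrics(val_probs, val_labels)
        row = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_auc": val_auc,
            "val_accuracy": metrics.accuracy,
            "val_precision": metrics.precision,
            "val_recall": metrics.recall,
            "val_f1": metrics.f1,
            "lr": lr,
        }
        history.epochs.append(row)
        if verbose:
            print(
                f"epoch {epoch:3d} loss {row['train_loss']:.4f} "
                f"val_auc {val_auc:.4f} lr {lr:.2e}"
            )
        if val_auc > best_auc + config.min_delta_auc:
            best_auc = val_auc
            best_state = model.get_state()
            best_epoch = epoch
            epochs_since_improvement = 0
        else:
            if val_auc > best_auc:  # track best weights even below min_delta
                best_auc = val_auc
                best_state = model.get_state()
                best_epoch = epoch
            epochs_since_improvement += 1
        if epochs_since_improvement >= config.patience_epochs:
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_epochs"

    model.set_state(best_state)
    history.best_epoch = best_epoch
    return model, history
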