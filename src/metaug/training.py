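"""Optimization protocol: BCE over all report positions, Adam with a cosine
learning-rate schedule, early stopping on validation F1, continuation on
augmented data, and budget-matched epochs for targeted augmentation.

Defaults follow the full-scale protocol (up to 1,000 epochs with 200 epochs
of patience, 10 continuation epochs at N = 10); bundled experiments run the
same code with smaller caps.  "Computation budget" is measured as
epochs × number of training patients, so a targeted strategy with a smaller
augmented dataset earns proportionally more continuation epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aggregator import MetastasisModel, PredictionSeries
from .augment import AugmentedDataset
from .autodiff import Adam, bce_with_logits
from .corpus import Patient
from .errors import ConfigurationError, InputError, IntegrityError


@dataclass
class TrainingConfig:
    max_epochs: int = 1000
    patience: int = 200
    augmented_epochs_base: int = 10
    learning_rate: float = 0.01
    schedule: str = "cosine"
    batch_size: int = 32
    minority_upsampling: bool = False
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.patience > self.max_epochs:
            raise ConfigurationError("patience must be <= max_epochs")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigurationError("decision_threshold must be in (0, 1)")
        if self.schedule not in ("cosine", "constant"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_validation_f1: float = 0.0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def binary_f1(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> float:
    """F1 of the positive class, pooled over all report positions.

    A prediction is positive iff its probability is >= threshold.  When the
    pool has neither positive gold labels nor positive predictions, F1 is
    defined as 0 and a warning is emitted.
    """
    probs = np.asarray(probabilities, dtype=float)
    gold = np.asarray(labels, dtype=int)
    if probs.shape != gold.shape:
        raise InputError("predictions and labels are misaligned")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (gold == 1)))
    fp = int(np.sum((pred == 1) & (gold == 0)))
    fn = int(np.sum((pred == 0) & (gold == 1)))
    if tp == 0 and fp == 0 and fn == 0:
        warnings.warn("no positive gold labels and no positive predictions; F1 := 0")
        return 0.0
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def evaluate_f1(
    model: MetastasisModel, patients: Sequence[Patient], threshold: float = 0.5
) -> float:
    """Pooled positive-class F1 of a model over a patient set."""
    if not patients:
        raise InputError("empty evaluation set")
    probs = model.batch_predict(list(patients))
    gold = [lab for p in patients for lab in p.labels]
    return binary_f1(np.concatenate(probs), np.array(gold), threshold)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


def _upsample_minority(patients: list[Patient]) -> list[Patient]:
    n_pos = sum(sum(p.labels) for p in patients)
    n_neg = sum(len(p.reports) for p in patients) - n_pos
    factor = max(0, round(n_neg / max(1, n_pos)) - 1)
    extra = [
        p for p in patients if p.reports and p.positive_fraction >= 0.5
    ] * factor
    return patients + extra


def _length_bucketed_batches(
    patients: list[Patient], batch_size: int, rng: np.random.Generator
) -> list[list[Patient]]:
    """Seeded minibatches grouped by timeline length.

    Padding a batch to its longest timeline wastes compute when lengths are
    mixed, so patients are ordered by (length, random tiebreak) before being
    chunked; the chunk order itself is then shuffled."""
    keys = rng.random(len(patients))
    order = sorted(
        range(len(patients)), key=lambda i: (len(patients[i].reports), keys[i])
    )
    chunks = [
        [patients[i] for i in order[s : s + batch_size]]
        for s in range(0, len(order), batch_size)
    ]
    chunk_order = rng.permutation(len(chunks))
    return [chunks[int(i)] for i in chunk_order]


def _run_epochs(
    model: MetastasisModel,
    train_patients: list[Patient],
    validation_patients: Sequence[Patient],
    config: TrainingConfig,
    n_epochs: int,
    history: TrainingHistory,
    include_initial: bool = False,
) -> None:
    """Shared epoch loop with best-validation-F1 checkpointing.

    Mutates ``model`` to the best checkpoint and fills ``history`` in place.
    Early stopping triggers after ``config.patience`` epochs without
    validation improvement (the caller passes n_epochs = max_epochs for the
    initial fit and an exact epoch count for continuation).
    """
    rng = np.random.default_rng(config.seed)
    n_batches = max(1, int(np.ceil(len(train_patients) / config.batch_size)))
    optimizer = Adam(
        model.trainable(),
        lr=config.learning_rate,
        schedule=config.schedule,
        total_steps=n_epochs * n_batches,
    )
    best_f1 = -1.0
    best_state = None
    best_epoch = -1
    if include_initial:
        best_f1 = evaluate_f1(model, validation_patients, config.decision_threshold)
        best_state = model.state_values()
        best_epoch = -1
    since_best = 0
    for epoch in range(n_epochs):
        batches = _length_bucketed_batches(
            train_patients, config.batch_size, rng
        )
        losses = []
        for batch in batches:
            logits, targets = model.batch_logits(batch)
            loss = bce_with_logits(logits, targets)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.value))
        val_f1 = evaluate_f1(model, validation_patients, config.decision_threshold)
        history.train_loss.append(float(np.mean(losses)))
        history.val_f1.append(val_f1)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_state = model.state_values()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_values(best_state)
    history.best_epoch = best_epoch
    history.best_validation_f1 = max(best_f1, 0.0)


def train(
    model: MetastasisModel,
    train_patients: Sequence[Patient],
    validation_patients: Sequence[Patient],
    config: TrainingConfig,
) -> tuple[MetastasisModel, TrainingHistory]:
    """Fit on original data with early stopping on validation F1."""
    if not train_patients or not validation_patients:
        raise InputError("train and validation sets must be non-empty")
    train_ids = {p.patient_id for p in train_patients}
    if train_ids & {p.patient_id for p in validation_patients}:
        raise IntegrityError("train and validation share patients")
    pool = list(train_patients)
    if config.minority_upsampling:
        pool = _upsample_minority(pool)
    history = TrainingHistory()
    _run_epochs(
        model, pool, validation_patients, config, config.max_epochs, history
    )
    return model, history


def continue_on_augmented(
    model: MetastasisModel,
    augmented: AugmentedDataset,
    validation_patients: Sequence[Patient],
    epochs: int,
    config: TrainingConfig,
) -> tuple[MetastasisModel, TrainingHistory]:
    """Resume optimization on the augmented dataset for exactly ``epochs``.

    Starts from the model previously fitted on the original data; the best
    checkpoint (including the starting point) is again chosen by validation
    F1, so continuation can only keep or improve validation performance.
    The validation set must be free of synthetic material.
    """
    if epochs < 1:
        raise ConfigurationError("continuation epochs must be >= 1")
    for p in validation_patients:
        if any(r.provenance == "synthetic" for r in p.reports):
            raise IntegrityError(
                f"validation patient {p.patient_id} contains synthetic reports"
            )
    pool = augmented.all_patients()
    history = TrainingHistory()
    cont_config = TrainingConfig(
        **{
            **config.__dict__,
            "max_epochs": epochs,
            "patience": epochs,
        }
    )
    _run_epochs(
        model,
        pool,
        validation_patients,
        cont_config,
        epochs,
        history,
        include_initial=True,
    )
    return model, history


def budget_matched_epochs(
    n_original: int,
    n_syn_vanilla: int,
    n_syn_targeted: int,
    base: int = 10,
) -> int:
    """Continuation epochs equalizing epochs × dataset-size with vanilla.

    Vanilla continuation trains ``base`` epochs on n_original + n_syn_vanilla
    patients; a targeted strategy with a smaller synthetic set gets
    round(base · (n_original + n_syn_vanilla) / (n_original + n_syn_targeted))
    epochs, at least 1.
    """
    if min(n_original, n_syn_vanilla, n_syn_targeted) < 0:
        raise ConfigurationError("counts must be >= 0")
    denom = n_original + n_syn_targeted
    if denom == 0:
        raise ConfigurationError("n_original + n_syn_targeted must be > 0")
    return max(1, round(base * (n_original + n_syn_vanilla) / denom))
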