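"""Subject-level splitting, imbalance resampling and the SGD training loop.

Sleep data is grouped: epochs within a subject are strongly dependent, so
train/test splits are made by whole subject, never by epoch, and the stored
within-subject temporal order is preserved.  Stage frequencies are heavily
skewed toward N2, so before training each night's epochs are rebalanced:
minority stages (W, N1, N3, REM) are randomly oversampled and N2 is
undersampled, with a hard cap per (night, stage) group.

The optimizer is plain minibatch stochastic gradient descent on the softmax
cross-entropy, with a stepwise-decaying learning rate
``lr(e) = lr_init * decay_factor ** floor(e / decay_every)`` and optional
global-norm gradient clipping to keep 300-step backpropagation through time
stable.  Given a fixed seed and thread count the loop is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .model import StagerModel, epochs_to_input
from .stages import StageLabel
from .synth import EpochRecord

__all__ = [
    "SplitPlan",
    "ResamplePolicy",
    "TrainSchedule",
    "TrainResult",
    "TrainingDiverged",
    "split_by_subject",
    "resample",
    "validation_folds",
    "learning_rate_at",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class SplitPlan:
    """Whole-subject partition of a cohort into train and test sets."""

    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    validation_fold_size: int = 4  # nights per validation fold

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_subjects", tuple(self.train_subjects))
        object.__setattr__(self, "test_subjects", tuple(self.test_subjects))
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(
                f"subjects in both train and test: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class ResamplePolicy:
    """Per-(night, stage) epoch cap with stage-wise over/under-sampling."""

    cap_per_stage_per_night: int = 200
    oversample_stages: frozenset[StageLabel] = frozenset(
        {StageLabel.W, StageLabel.N1, StageLabel.N3, StageLabel.REM}
    )
    undersample_stages: frozenset[StageLabel] = frozenset({StageLabel.N2})

    def __post_init__(self) -> None:
        if self.cap_per_stage_per_night < 1:
            raise ValueError("cap_per_stage_per_night must be >= 1")
        object.__setattr__(self, "oversample_stages",
                           frozenset(self.oversample_stages))
        object.__setattr__(self, "undersample_stages",
                           frozenset(self.undersample_stages))


@dataclass(frozen=True)
class TrainSchedule:
    """SGD schedule; defaults follow the canonical training regimen."""

    epochs: int = 100
    batch_size: int = 10
    lr_init: float = 0.015
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 20
    clip_grad_norm: float | None = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or min(self.batch_size, self.lr_decay_every) < 1:
            raise ValueError("epochs must be >= 0; batch/decay sizes >= 1")
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1]")


@dataclass
class TrainResult:
    """Final model plus per-epoch loss/accuracy curves."""

    model: StagerModel
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)

    def curves(self) -> dict[str, list[float]]:
        return {
            "epoch": list(range(len(self.train_loss))),
            "lr": self.learning_rates,
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
            "val_loss": self.val_loss,
            "val_acc": self.val_acc,
        }


def split_by_subject(
    records: Sequence[EpochRecord], plan: SplitPlan
) -> tuple[list[EpochRecord], list[EpochRecord]]:
    """Partition records by whole subject, preserving stored order.

    Every record's subject must be covered by the plan; an uncovered
    subject raises ``ValueError``.
    """
    train_set = set(plan.train_subjects)
    test_set = set(plan.test_subjects)
    covered = train_set | test_set
    uncovered = sorted({r.subject_id for r in records} - covered)
    if uncovered:
        raise ValueError(f"subjects not covered by the split plan: {uncovered}")
    train = [r for r in records if r.subject_id in train_set]
    test = [r for r in records if r.subject_id in test_set]
    return train, test


def resample(
    records: Sequence[EpochRecord],
    policy: ResamplePolicy,
    rng: np.random.Generator,
) -> list[EpochRecord]:
    """Rebalance stage counts per night under the policy cap.

    For each (subject, night, stage) group: groups larger than the cap are
    downsampled without replacement; groups smaller than the cap whose stage
    is in ``oversample_stages`` keep all originals and add duplicates drawn
    with replacement until the cap is reached; other groups pass through.
    Deterministic given the rng state.
    """
    groups: dict[tuple[str, str, StageLabel], list[EpochRecord]] = {}
    order: list[tuple[str, str, StageLabel]] = []
    for rec in records:
        key = (rec.subject_id, rec.night_id, rec.stage)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    cap = policy.cap_per_stage_per_night
    out: list[EpochRecord] = []
    for key in order:
        group = groups[key]
        n = len(group)
        stage = key[2]
        if n > cap:
            keep = np.sort(rng.choice(n, size=cap, replace=False))
            out.extend(group[i] for i in keep)
        elif n < cap and stage in policy.oversample_stages:
            out.extend(group)
            extra = rng.choice(n, size=cap - n, replace=True)
            out.extend(group[i] for i in extra)
        else:
            out.extend(group)
    return out


def validation_folds(
    records: Sequence[EpochRecord], n_folds: int
) -> list[tuple[list[EpochRecord], list[EpochRecord]]]:
    """Night-level cross-validation folds: (fit, holdout) record pairs.

    Nights are taken in stored order and split into ``n_folds`` contiguous
    groups (remainders spill into the earliest folds, so 48 nights in 12
    folds gives exactly 4 nights per fold).  Folds are disjoint and cover
    every night.  Requires 2 <= n_folds <= number of nights.
    """
    nights: list[tuple[str, str]] = []
    by_night: dict[tuple[str, str], list[EpochRecord]] = {}
    for rec in records:
        key = (rec.subject_id, rec.night_id)
        if key not in by_night:
            by_night[key] = []
            nights.append(key)
        by_night[key].append(rec)
    if n_folds < 2:
        raise ValueError("need at least 2 folds (1 fold leaves no fit set)")
    if n_folds > len(nights):
        raise ValueError(
            f"cannot split {len(nights)} nights into {n_folds} folds"
        )
    night_folds = [list(chunk) for chunk in
                   np.array_split(np.arange(len(nights)), n_folds)]
    folds = []
    for fold_idx in night_folds:
        holdout_keys = {nights[i] for i in fold_idx}
        fit = [r for key in nights if key not in holdout_keys
               for r in by_night[key]]
        holdout = [r for key in nights if key in holdout_keys
                   for r in by_night[key]]
        folds.append((fit, holdout))
    return folds


def learning_rate_at(schedule: TrainSchedule, epoch: int) -> float:
    """Stepwise-decayed learning rate at a (0-based) training epoch."""
    return schedule.lr_init * schedule.lr_decay_factor ** (
        epoch // schedule.lr_decay_every
    )


def _global_grad_norm(model: StagerModel) -> float:
    total = 0.0
    for layer, name in model.parameters():
        g = layer.grads[name]
        total += float(np.sum(g.astype(np.float64) ** 2))
    return float(np.sqrt(total))


def train(
    model: StagerModel,
    train_records: Sequence[EpochRecord],
    schedule: TrainSchedule,
    validation: Sequence[EpochRecord] | None = None,
) -> TrainResult:
    """Minibatch SGD on softmax cross-entropy over stage-labelled epochs.

    Records are shuffled each epoch (the stored order is untouched);
    per-epoch training loss/accuracy and, when a validation set is given,
    validation loss/accuracy are recorded.  A non-finite loss aborts with
    ``TrainingDiverged``.  A 0-epoch schedule returns the model unchanged.
    """
    result = TrainResult(model=model)
    if schedule.epochs == 0:
        return result

    x = epochs_to_input(train_records, model.config).astype(np.float32)
    y = np.array([int(r.stage) for r in train_records], dtype=np.int64)
    if validation is not None and len(validation) > 0:
        x_val = epochs_to_input(validation, model.config).astype(np.float32)
        y_val = np.array([int(r.stage) for r in validation], dtype=np.int64)
    else:
        x_val = y_val = None

    rng = np.random.default_rng(schedule.seed)
    n = x.shape[0]
    for epoch in range(schedule.epochs):
        lr = learning_rate_at(schedule, epoch)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, schedule.batch_size):
            idx = perm[start:start + schedule.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grads()
            logits = model.forward(xb, training=True, rng=rng)
            loss, probs, dlogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch starting {start} "
                    f"(lr={lr:g}); consider a lower learning rate or gradient "
                    f"clipping"
                )
            model.backward(dlogits)
            if schedule.clip_grad_norm:
                norm = _global_grad_norm(model)
                if norm > schedule.clip_grad_norm:
                    scale = schedule.clip_grad_norm / norm
                    for layer, name in model.parameters():
                        layer.grads[name] *= scale
            for layer, name in model.parameters():
                layer.params[name] -= (lr * layer.grads[name]).astype(
                    layer.params[name].dtype
                )
            epoch_loss += loss * len(idx)
            correct += int(np.sum(np.argmax(probs, axis=1) == yb))
        result.learning_rates.append(lr)
        result.train_loss.append(epoch_loss / n)
        result.train_acc.append(correct / n)
        if x_val is not None:
            probs_val = model.predict_proba(x_val)
            eps = 1e-12
            v_loss = float(-np.mean(
                np.log(probs_val[np.arange(len(y_val)), y_val] + eps)
            ))
            v_acc = float(np.mean(np.argmax(probs_val, axis=1) == y_val))
            result.val_loss.append(v_loss)
            result.val_acc.append(v_acc)
        else:
            result.val_loss.append(float("nan"))
            result.val_acc.append(float("nan"))
    return result
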