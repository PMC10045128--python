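"""Dice-loss training protocol: Adam, decaying learning rate, subject-level
splits, and five-fold cross-validation.

The protocol trains slice-wise with mini-batches of 8 for 100 epochs; the
learning rate starts at 5e-4 and decays to 1e-4 once the epoch number exceeds
20 (linear decay by default, a step schedule behind a config switch). The
loss is the soft Dice loss 1 - kappa_D computed jointly over all pixels of a
batch. Subjects are partitioned 6:2:2 into train/validation/test at the
subject level only — slices of one animal never straddle partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .augment import augment_stream
from .network import RUNet


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 100
    lr_initial: float = 5e-4
    lr_final: float = 1e-4
    lr_decay_start_epoch: int = 20
    lr_schedule: str = "linear"  # or "step"
    split_ratios: tuple[float, float, float] = (6.0, 2.0, 2.0)
    folds: int = 5
    seed: int = 0
    per_epoch_factor: int = 10
    dice_smooth: float = 1e-6

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.lr_final > self.lr_initial:
            raise ValueError("lr_final must not exceed lr_initial")
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")
        if self.lr_schedule not in ("linear", "step"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")
        if self.per_epoch_factor < 1:
            raise ValueError("per_epoch_factor must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_pixel_accuracy: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)


def dice_loss(pred: np.ndarray, gt: np.ndarray, smooth: float = 1e-6) -> float:
    """Soft Dice loss 1 - kappa_D on probabilities; see :func:`nn.soft_dice_loss`."""
    loss, _ = nn.soft_dice_loss(np.asarray(pred, dtype=np.float64),
                                np.asarray(gt, dtype=np.float64), eps=smooth)
    return loss


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a 1-based epoch number.

    Constant at ``lr_initial`` through ``lr_decay_start_epoch``; then either a
    linear ramp reaching ``lr_final`` at the last epoch (default) or a single
    step down to ``lr_final``.
    """
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} out of range 1..{cfg.epochs}")
    if epoch <= cfg.lr_decay_start_epoch:
        return cfg.lr_initial
    if cfg.lr_schedule == "step":
        return cfg.lr_final
    span = cfg.epochs - cfg.lr_decay_start_epoch
    frac = (epoch - cfg.lr_decay_start_epoch) / span
    return cfg.lr_initial + frac * (cfg.lr_final - cfg.lr_initial)


def split_subjects(subject_ids: Sequence[str], ratios: Sequence[float] = (6, 2, 2),
                   seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Disjoint, exhaustive subject-level split with largest-remainder rounding."""
    ids = list(subject_ids)
    if len(ids) < len(ratios):
        raise ValueError(f"need at least {len(ratios)} subjects, got {len(ids)}")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    total = float(sum(ratios))
    exact = [len(ids) * r / total for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    # ensure each part is non-empty, then hand out remainders by fractional part
    for i, s in enumerate(sizes):
        if s == 0:
            sizes[i] = 1
    remainder = len(ids) - sum(sizes)
    if remainder < 0:
        raise ValueError("too few subjects for the requested ratios")
    frac_order = np.argsort([-(e - np.floor(e)) for e in exact], kind="stable")
    for j in range(remainder):
        sizes[frac_order[j % len(sizes)]] += 1
    parts: list[list[str]] = []
    start = 0
    for s in sizes:
        parts.append([ids[i] for i in order[start:start + s]])
        start += s
    return parts[0], parts[1], parts[2]


def make_folds(subject_ids: Sequence[str], k: int = 5,
               seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """k subject-level cross-validation folds; each subject validates exactly once."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(subject_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, k)
    folds = []
    for chunk in chunks:
        val = [ids[i] for i in chunk]
        val_set = set(val)
        train = [ids[i] for i in order if ids[i] not in val_set]
        folds.append((train, val))
    return folds


def _binary_dice(pred_bin: np.ndarray, gt: np.ndarray) -> float:
    tp = float(np.count_nonzero(pred_bin & (gt > 0)))
    denom = float(np.count_nonzero(pred_bin) + np.count_nonzero(gt))
    return 1.0 if denom == 0 else 2.0 * tp / denom


def _evaluate_epoch(model: RUNet, pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                    batch_size: int, smooth: float) -> tuple[float, float, float]:
    """(soft loss, binarized Dice, pixel accuracy) over a slice set, inference mode."""
    losses, dices, accs = [], [], []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        x = np.stack([img for img, _ in chunk])[:, None]
        g = np.stack([msk for _, msk in chunk])[:, None].astype(np.float32)
        p = model.forward(x, training=False)
        loss, _ = nn.soft_dice_loss(p, g, eps=smooth)
        losses.append(loss)
        pb = p >= 0.5
        dices.append(_binary_dice(pb, g))
        accs.append(float((pb == (g > 0)).mean()))
    return float(np.mean(losses)), float(np.mean(dices)), float(np.mean(accs))


def train(model: RUNet, train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
          val_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
          cfg: TrainConfig) -> tuple[RUNet, TrainHistory]:
    """Optimize the soft Dice loss with Adam over an augmented slice stream.

    ``train_pairs`` / ``val_pairs`` are (image, mask) 2-D slice pairs, images
    already z-scored. Each epoch draws ``per_epoch_factor`` fresh augmented
    variants of every training slice, shuffles them, and steps per mini-batch
    with the scheduled learning rate. Validation slices are never augmented.
    Returns the model restored to its best-validation-Dice checkpoint and the
    per-epoch history. Raises on empty training data; aborts on a non-finite
    loss.
    """
    if len(train_pairs) == 0:
        raise ValueError("training set is empty")
    optimizer = nn.Adam(lr=cfg.lr_initial)
    history = TrainHistory()
    rng = np.random.default_rng(cfg.seed)
    best_dice, best_state = -1.0, None

    for epoch in range(1, cfg.epochs + 1):
        lr = learning_rate(epoch, cfg)
        optimizer.lr = lr
        aug_seed = int(rng.integers(0, 2**31 - 1))
        epoch_pairs = list(augment_stream(train_pairs, cfg.per_epoch_factor, aug_seed))
        order = rng.permutation(len(epoch_pairs))
        epoch_losses: list[float] = []
        epoch_dices: list[float] = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = np.stack([epoch_pairs[i][0] for i in idx])[:, None].astype(np.float32)
            g = np.stack([epoch_pairs[i][1] for i in idx])[:, None].astype(np.float32)
            p = model.forward(x, training=True)
            loss, dgrad = nn.soft_dice_loss(p, g, eps=cfg.dice_smooth)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}")
            model.backward(dgrad)
            optimizer.step(model.named_parameters())
            epoch_losses.append(loss)
            epoch_dices.append(_binary_dice(p >= 0.5, g))

        # training-curve points come from the training batches themselves,
        # as is conventional; validation is a clean inference pass
        tr_loss, tr_dice = float(np.mean(epoch_losses)), float(np.mean(epoch_dices))
        history.train_loss.append(tr_loss)
        history.train_dice.append(tr_dice)
        history.learning_rates.append(lr)
        if len(val_pairs) > 0:
            va_loss, va_dice, va_acc = _evaluate_epoch(model, list(val_pairs),
                                                       cfg.batch_size, cfg.dice_smooth)
        else:
            va_loss, va_dice, va_acc = tr_loss, tr_dice, float("nan")
        history.val_loss.append(va_loss)
        history.val_dice.append(va_dice)
        history.val_pixel_accuracy.append(va_acc)
        if va_dice > best_dice:
            best_dice = va_dice
            best_state = model.state_copy()

    if best_state is not None:
        model.load_state(best_state)
    return model, history
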