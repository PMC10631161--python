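"""Dice-loss training: optimizer schedule, slab sampling, case split.

Training follows the source protocol for this task: Adam with weight decay
1e-5, learning rate decaying from 2e-4 at epoch 0 to 4e-7 at epoch 999,
batch size 2, random seed 1000, an 80/20 case-level split, and random
32-slice slabs drawn from each volume as network inputs.  Only the two
learning-rate endpoints are prescribed; the default schedule interpolates
log-linearly between them (linear and cosine schedules are also provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor
from .network import SegmentationNetwork

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainingCase",
    "Adam",
    "dice_loss",
    "batch_dice_loss",
    "soft_dice",
    "lr_at_epoch",
    "sample_slab",
    "sample_slab_biased",
    "split_cases",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 2
    lr_initial: float = 2e-4
    lr_final: float = 4e-7
    weight_decay: float = 1e-5
    slab_depth: int = 32
    seed: int = 1000
    train_fraction: float = 0.8
    schedule: str = "log"  # "log" | "linear" | "cosine"
    #: epochs of linear learning-rate warmup ahead of the decay (0 = none)
    warmup_epochs: int = 0
    #: probability that a training slab is drawn around a foreground slice
    #: (0 = uniform start index, the plain protocol)
    fg_slab_bias: float = 0.0
    adam_beta2: float = 0.999

    def __post_init__(self):
        if not (0 < self.lr_final <= self.lr_initial):
            raise ValueError("require 0 < lr_final <= lr_initial")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.slab_depth % 16 != 0:
            raise ValueError("slab_depth must be divisible by 16")
        if self.schedule not in ("log", "linear", "cosine"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if not (0 <= self.warmup_epochs < self.epochs):
            raise ValueError("warmup_epochs must lie in [0, epochs)")
        if not (0.0 <= self.fg_slab_bias <= 1.0):
            raise ValueError("fg_slab_bias must lie in [0, 1]")


@dataclass
class TrainingCase:
    """A preprocessed (normalized image, binary mask) pair, axes (x, y, z)."""

    image: np.ndarray
    mask: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


@dataclass
class TrainState:
    """Per-epoch history of a training run."""

    epochs: list[int] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    steps: int = 0

    def record(self, epoch: int, lr: float, loss: float) -> None:
        self.epochs.append(epoch)
        self.lrs.append(lr)
        self.losses.append(loss)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def soft_dice(pred, target, eps: float = 1e-5):
    """Soft Dice overlap (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps).

    Accepts autodiff tensors (returns a Tensor on the graph) or plain
    arrays (returns a float).
    """
    if isinstance(pred, Tensor):
        t = Tensor(np.asarray(target, np.float32))
        num = (pred * t).sum() * 2.0 + eps
        den = pred.sum() + t.sum() + eps
        return num / den
    pred = np.asarray(pred, np.float64)
    target = np.asarray(target, np.float64)
    return float((2.0 * (pred * target).sum() + eps) / (pred.sum() + target.sum() + eps))


def dice_loss(pred, target, eps: float = 1e-5):
    """1 - soft Dice; the training loss, robust to extreme class imbalance."""
    p_shape = pred.shape if hasattr(pred, "shape") else np.shape(pred)
    if tuple(p_shape) != tuple(np.shape(target)):
        raise ValueError(f"shape mismatch: {p_shape} vs {np.shape(target)}")
    return 1.0 - soft_dice(pred, target, eps)


# ---------------------------------------------------------------------
# schedule / sampling / split
# ---------------------------------------------------------------------

def lr_at_epoch(e: int | float, cfg: TrainConfig) -> float:
    """Learning rate at epoch ``e``.

    Without warmup the schedule interpolates between the two printed
    endpoints (met exactly at epochs 0 and ``epochs - 1``); with warmup the
    rate climbs linearly to ``lr_initial`` first, then decays.
    """
    if e < 0 or e > cfg.epochs - 1:
        raise ValueError(f"epoch {e} outside [0, {cfg.epochs - 1}]")
    if cfg.epochs == 1:
        return cfg.lr_initial
    if e < cfg.warmup_epochs:
        return float(cfg.lr_initial * (e + 1) / cfg.warmup_epochs)
    span = cfg.epochs - 1 - cfg.warmup_epochs
    frac = (e - cfg.warmup_epochs) / span if span > 0 else 1.0
    if cfg.schedule == "log":
        return float(cfg.lr_initial * (cfg.lr_final / cfg.lr_initial) ** frac)
    if cfg.schedule == "linear":
        return float(cfg.lr_initial + (cfg.lr_final - cfg.lr_initial) * frac)
    # cosine
    return float(cfg.lr_final + 0.5 * (cfg.lr_initial - cfg.lr_final) * (1 + np.cos(np.pi * frac)))


def sample_slab(
    image: np.ndarray,
    mask: np.ndarray,
    slab_depth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a random contiguous block of ``slab_depth`` axial slices.

    When the volume is shorter than the slab, both image and mask are
    symmetrically zero-padded along z.
    """
    if slab_depth < 1:
        raise ValueError("slab_depth must be >= 1")
    D = image.shape[2]
    if D >= slab_depth:
        start = int(rng.integers(0, D - slab_depth + 1))
        return (
            image[:, :, start : start + slab_depth],
            mask[:, :, start : start + slab_depth],
        )
    lo = (slab_depth - D) // 2
    hi = slab_depth - D - lo
    pad = ((0, 0), (0, 0), (lo, hi))
    return np.pad(image, pad), np.pad(mask, pad)


def sample_slab_biased(
    image: np.ndarray,
    mask: np.ndarray,
    slab_depth: int,
    rng: np.random.Generator,
    fg_prob: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Slab sampler with optional foreground bias.

    With probability ``fg_prob`` the window is drawn uniformly among the
    starts whose slab contains a foreground slice (a standard countermeasure
    to extreme class imbalance); otherwise, and whenever the volume has no
    foreground, it falls back to the uniform :func:`sample_slab`.
    """
    D = image.shape[2]
    if D > slab_depth and fg_prob > 0 and rng.random() < fg_prob:
        z_fg = np.flatnonzero(mask.sum(axis=(0, 1)))
        if len(z_fg):
            z = int(rng.choice(z_fg))
            lo = max(0, z - slab_depth + 1)
            hi = min(z, D - slab_depth)
            start = int(rng.integers(lo, hi + 1))
            return (
                image[:, :, start : start + slab_depth],
                mask[:, :, start : start + slab_depth],
            )
    return sample_slab(image, mask, slab_depth, rng)


def split_cases(cases: Sequence, train_fraction: float, seed: int):
    """Shuffled, disjoint, exhaustive case-level split."""
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    order = np.random.default_rng(seed).permutation(len(cases))
    n_train = int(round(train_fraction * len(cases)))
    n_train = min(max(n_train, 1), len(cases) - 1)
    train_idx, test_idx = order[:n_train], order[n_train:]
    return [cases[i] for i in train_idx], [cases[i] for i in test_idx]


# ---------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------

class Adam:
    """Adam with decoupled L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for _, p in params] if params and isinstance(params[0], tuple) else list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# ---------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------

def train(
    model: SegmentationNetwork,
    cases: Sequence[TrainingCase],
    cfg: TrainConfig,
    *,
    max_steps: int | None = None,
    stop_loss: float | None = None,
    callback: Callable[[int, float, float], None] | None = None,
) -> TrainState:
    """Train ``model`` in place on preprocessed cases.

    One epoch is one shuffled pass over the cases, one freshly sampled slab
    per case, grouped into batches of ``cfg.batch_size``.  All randomness
    (slab starts, shuffling, dropout) derives from ``cfg.seed``, so repeated
    runs are bit-identical in single-threaded execution.

    ``max_steps`` caps the number of optimizer updates and ``stop_loss``
    stops early once an epoch's mean loss falls at or below it (both
    intended for scaled-down runs).
    """
    if len(cases) == 0:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(cfg.seed)
    s_slab, s_shuffle, s_drop = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3))
    rng_slab = np.random.default_rng(s_slab)
    rng_shuffle = np.random.default_rng(s_shuffle)
    model.reseed_dropout(s_drop)
    model.train()

    opt = Adam(
        list(model.parameters()),
        lr=cfg.lr_initial,
        betas=(0.9, cfg.adam_beta2),
        weight_decay=cfg.weight_decay,
    )
    state = TrainState()
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(epoch, cfg)
        order = rng_shuffle.permutation(len(cases))
        epoch_losses: list[float] = []
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            slabs = [
                sample_slab_biased(
                    cases[i].image, cases[i].mask, cfg.slab_depth, rng_slab, cfg.fg_slab_bias
                )
                for i in idx
            ]
            xb = np.stack([s[0] for s in slabs])[:, None].astype(np.float32)
            yb = np.stack([s[1] for s in slabs])[:, None].astype(np.float32)
            pred = model.forward(xb)
            loss = batch_dice_loss(pred, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            state.steps += 1
            if max_steps is not None and state.steps >= max_steps:
                break
        mean_loss = float(np.mean(epoch_losses))
        state.record(epoch, opt.lr, mean_loss)
        if callback is not None:
            callback(epoch, opt.lr, mean_loss)
        if max_steps is not None and state.steps >= max_steps:
            break
        if stop_loss is not None and mean_loss <= stop_loss:
            break
    return state


def batch_dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss computed jointly over the whole batch (graph tensor).

    Treating the batch as one voxel set keeps slabs without any foreground
    well-behaved: they only add to the denominator, instead of contributing
    an irreducible loss of ~1 each as a per-slab Dice would.  The smoothing
    term of 1 keeps the all-background batch finite and decreasing as the
    predicted mass shrinks.
    """
    pf = pred.reshape(-1)
    tf = Tensor(np.asarray(target, np.float32).reshape(-1))
    num = (pf * tf).sum() * 2.0 + smooth
    den = pf.sum() + tf.sum() + smooth
    return 1.0 - num / den
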