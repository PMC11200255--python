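"""Training loop for the context explanation network.

Each presentation of a complex is voxelized afresh under a random rigid
augmentation (rotation + translation of at most ``max_shift`` A), the network
predicts per-term weights, and the smooth-L1 loss between the experimental
affinity (pK units) and the linear combination ``w . t`` is backpropagated
through the weight head (the precalculated terms are fixed inputs). The
optimizer is SGD with momentum and weight decay under a step learning-rate
decay, with the production defaults the method prescribes: lr 0.01, weight
decay 1e-4, momentum 0.9, batch 25, StepLR(80, 0.1), 250 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import nn
from .cenmodel import CENModel
from .structio import ComplexStructure
from .terms import TermVector
from .voxelize import GridConfig, sample_augmentation, voxelize

__all__ = ["TrainingConfig", "TrainingExample", "TrainingHistory",
           "smooth_l1", "pearson", "train", "evaluate"]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 250
    batch_size: int = 25
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    lr_step: int = 80
    lr_gamma: float = 0.1
    beta: float = 1.0          # smooth-L1 transition, pK units
    max_shift: float = 2.0     # augmentation translation bound, A
    augment: bool = True
    max_steps: int | None = None  # optional cap on total optimizer steps
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_step) <= 0:
            raise ValueError("epochs, batch_size and lr_step must be positive")
        if min(self.learning_rate, self.lr_gamma, self.beta) <= 0:
            raise ValueError("learning_rate, lr_gamma and beta must be positive")
        if self.weight_decay < 0 or not 0 <= self.momentum < 1 or self.max_shift < 0:
            raise ValueError("invalid optimizer/augmentation settings")


@dataclass
class TrainingExample:
    """One (structure, scaled terms, label) triple."""

    complex: ComplexStructure
    scaled_terms: TermVector
    pk: float

    def __post_init__(self):
        if not self.scaled_terms.scaled:
            raise ValueError(f"{self.complex.entry_id}: terms must be scaled")


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_lr: list[float] = field(default_factory=list)
    steps: int = 0


def smooth_l1(predicted, observed, beta: float = 1.0) -> float:
    """Smooth-L1 (Huber-style) loss, averaged over the batch.

    ``0.5 r^2 / beta`` for ``|r| < beta`` else ``|r| - 0.5 beta``, with
    ``r = predicted - observed``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = np.atleast_1d(np.asarray(predicted, float) - np.asarray(observed, float))
    a = np.abs(r)
    return float(np.where(a < beta, 0.5 * r * r / beta, a - 0.5 * beta).mean())


def _smooth_l1_grad(r: np.ndarray, beta: float) -> np.ndarray:
    return np.clip(r / beta, -1.0, 1.0) / r.size


def pearson(predictions, observations) -> float:
    """Pearson product-moment correlation; errors on degenerate input."""
    x = np.asarray(predictions, float)
    y = np.asarray(observations, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def _batch_grids(examples, grid_config, transforms):
    grids = [voxelize(ex.complex, grid_config, transform=t).densities
             for ex, t in zip(examples, transforms)]
    return np.stack(grids)


def train(model: CENModel, examples: list[TrainingExample],
          config: TrainingConfig,
          grid_config: GridConfig | None = None) -> TrainingHistory:
    """Train in place; returns the per-epoch loss/learning-rate history.

    Reproducible under ``config.seed``: the seed drives example shuffling and
    the per-presentation augmentation transforms. With augmentation off,
    epochs are bitwise repeatable.
    """
    if not examples:
        raise ValueError("empty training set")
    grid_config = grid_config or GridConfig(
        dim=model.config.grid_dim,
        resolution=48 * 0.5 / model.config.grid_dim)
    terms_matrix = np.stack([ex.scaled_terms.values for ex in examples])
    labels = np.array([ex.pk for ex in examples], float)

    rng = np.random.default_rng(config.seed)
    # without augmentation every presentation of an example yields the same
    # grid, so voxelize once up front
    grid_cache = (np.stack([voxelize(ex.complex, grid_config).densities
                            for ex in examples])
                  if not config.augment else None)
    optimizer = nn.SGD(model.parameters(), lr=config.learning_rate,
                       momentum=config.momentum,
                       weight_decay=config.weight_decay)
    scheduler = nn.StepLR(optimizer, config.lr_step, config.lr_gamma)
    history = TrainingHistory()

    for epoch in range(config.epochs):
        scheduler.set_epoch(epoch)
        order = rng.permutation(len(examples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            if config.max_steps is not None and history.steps >= config.max_steps:
                break
            idx = order[start:start + config.batch_size]
            batch = [examples[i] for i in idx]
            if config.augment:
                transforms = [sample_augmentation(rng, config.max_shift)
                              for _ in idx]
                grids = _batch_grids(batch, grid_config, transforms)
            else:
                grids = grid_cache[idx]
            weights = model.forward(grids, train=True)
            t = terms_matrix[idx]
            preds = (weights * t).sum(axis=1)
            r = preds - labels[idx]
            losses.append(smooth_l1(preds, labels[idx], config.beta))
            if not np.isfinite(losses[-1]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {history.steps}")
            dpred = _smooth_l1_grad(r, config.beta)
            optimizer.zero_grad()
            model.backward(dpred[:, None] * t)
            optimizer.step()
            history.steps += 1
        if losses:
            history.epoch_loss.append(float(np.mean(losses)))
            history.epoch_lr.append(optimizer.lr)
        if config.max_steps is not None and history.steps >= config.max_steps:
            break
    return history


def evaluate(model: CENModel, examples: list[TrainingExample],
             grid_config: GridConfig | None = None) -> np.ndarray:
    """Deterministic (no-augmentation) affinity predictions for examples."""
    grid_config = grid_config or GridConfig(
        dim=model.config.grid_dim,
        resolution=48 * 0.5 / model.config.grid_dim)
    preds = []
    for start in range(0, len(examples), 50):
        batch = examples[start:start + 50]
        grids = _batch_grids(batch, grid_config, [None] * len(batch))
        weights = model.forward(grids, train=False)
        t = np.stack([ex.scaled_terms.values for ex in batch])
        preds.extend((weights * t).sum(axis=1))
    return np.array(preds)
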