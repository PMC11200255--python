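"""The context explanation network (CEN) and the linear-combination predictor.

A convolutional backbone maps the voxelized complex to a vector of per-term
weights ``w``; the predicted affinity is the pure linear combination
``w . t`` of those weights with the complex's precalculated scaled terms
``t`` (no intercept), so the prediction decomposes exactly into per-term
contributions ``w_j * t_j``.

The backbone is specified as configuration data (a layer list), so tiny
desk-scale networks and the production network share one code path. The
production configuration reproduces the default2018-style trunk
(pool - conv3 - conv1 units with 32/64/128 filters on a 28-channel 48^3
grid) ending in two parallel fully connected heads of ``out_terms`` outputs
each, the vector analogue of the parent architecture's two scalar output
heads; the weight vector is read from the first head. With 144 output terms
this stack has exactly 8,269,024 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .terms import TermVector
from .voxelize import VoxelGrid

__all__ = ["ModelConfig", "WeightVector", "Prediction", "CENModel",
           "build_model", "predict_weights", "predict_affinity",
           "save_checkpoint", "load_checkpoint"]

PRODUCTION_TRUNK = [
    ["pool", 2], ["conv", 32, 3], ["relu"], ["conv", 32, 1], ["relu"],
    ["pool", 2], ["conv", 64, 3], ["relu"], ["conv", 64, 1], ["relu"],
    ["pool", 2], ["conv", 128, 3], ["relu"],
]

TINY_TRUNK = [
    ["pool", 2], ["conv", 8, 3], ["relu"],
    ["pool", 2],
]


@dataclass(frozen=True)
class ModelConfig:
    """Backbone specification: input grid shape, trunk layers, output width."""

    grid_channels: int = 28
    grid_dim: int = 48
    trunk: tuple = tuple(map(tuple, PRODUCTION_TRUNK))
    out_terms: int = 144
    n_heads: int = 2

    def __post_init__(self):
        object.__setattr__(self, "trunk", tuple(map(tuple, self.trunk)))
        for spec in self.trunk:
            if spec[0] not in {"pool", "conv", "relu"}:
                raise ValueError(f"unknown trunk layer {spec!r}")

    @classmethod
    def production(cls, out_terms: int = 144) -> "ModelConfig":
        return cls(out_terms=out_terms)

    @classmethod
    def tiny(cls, grid_channels: int, grid_dim: int, out_terms: int,
             trunk=None, n_heads: int = 1) -> "ModelConfig":
        return cls(grid_channels=grid_channels, grid_dim=grid_dim,
                   trunk=tuple(map(tuple, TINY_TRUNK if trunk is None else trunk)),
                   out_terms=out_terms, n_heads=n_heads)

    def to_dict(self) -> dict:
        return {"grid_channels": self.grid_channels, "grid_dim": self.grid_dim,
                "trunk": [list(s) for s in self.trunk],
                "out_terms": self.out_terms, "n_heads": self.n_heads}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(grid_channels=d["grid_channels"], grid_dim=d["grid_dim"],
                   trunk=tuple(map(tuple, d["trunk"])),
                   out_terms=d["out_terms"], n_heads=d["n_heads"])


@dataclass
class WeightVector:
    """The CEN output: one weight per registry term for one complex."""

    entry_id: str
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class Prediction:
    """Decomposed affinity prediction: ``affinity == sum(contributions)``."""

    entry_id: str
    affinity: float
    per_term_contributions: np.ndarray
    weights: WeightVector
    scaled_terms: TermVector


class CENModel:
    """A built CEN: trunk + multi-head affine map, with seeded parameters."""

    def __init__(self, config: ModelConfig, rng_seed: int):
        self.config = config
        self.seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        layers: list[nn.Layer] = []
        shape = (config.grid_channels, config.grid_dim)
        for n, spec in enumerate(config.trunk):
            kind = spec[0]
            if kind == "pool":
                layer = nn.AvgPool3d(spec[1])
            elif kind == "conv":
                layer = nn.Conv3d(shape[0], spec[1], spec[2], rng, name=f"trunk{n}")
            else:
                layer = nn.ReLU()
            shape = layer.out_shape(shape)
            layers.append(layer)
        layers.append(nn.Flatten())
        flat = layers[-1].out_shape(shape)[0]
        self.network = nn.Sequential(layers)
        self.head = nn.Linear(flat, config.n_heads * config.out_terms, rng,
                              name="head")

    def parameters(self) -> list[nn.Parameter]:
        return self.network.parameters() + self.head.parameters()

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, grids: np.ndarray, train: bool = False) -> np.ndarray:
        """Batched forward pass; returns the weight bank (batch, out_terms)."""
        if grids.ndim == 4:
            grids = grids[None]
        expect = (self.config.grid_channels,) + (self.config.grid_dim,) * 3
        if grids.shape[1:] != expect:
            raise ValueError(f"grid shape {grids.shape[1:]} does not match "
                             f"model input {expect}")
        out = self.head.forward(self.network.forward(grids, train=train),
                                train=train)
        return out[:, :self.config.out_terms]

    def backward(self, grad_weights: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the weight bank."""
        full = np.zeros((grad_weights.shape[0],
                         self.config.n_heads * self.config.out_terms))
        full[:, :self.config.out_terms] = grad_weights
        self.network.backward(self.head.backward(full))


def build_model(config: ModelConfig, rng_seed: int = 0) -> CENModel:
    """Construct a CEN with deterministic, seeded parameter initialization."""
    return CENModel(config, rng_seed)


def predict_weights(model: CENModel, grid: VoxelGrid) -> WeightVector:
    """Evaluation-mode weight prediction for one voxelized complex."""
    out = model.forward(np.asarray(grid.densities, float), train=False)[0]
    return WeightVector(entry_id=grid.metadata.get("entry_id", ""), weights=out)


def predict_affinity(weights: WeightVector, scaled_terms: TermVector) -> Prediction:
    """Affinity = w . t over scaled terms, with exact per-term decomposition."""
    if not scaled_terms.scaled:
        raise ValueError("predict_affinity requires a scaled term vector")
    if len(weights.weights) != len(scaled_terms.values):
        raise ValueError("weight/term length mismatch")
    contributions = weights.weights * scaled_terms.values
    return Prediction(entry_id=scaled_terms.entry_id,
                      affinity=float(contributions.sum()),
                      per_term_contributions=contributions,
                      weights=weights, scaled_terms=scaled_terms)


def save_checkpoint(model: CENModel, path, registry=None, scaling=None,
                    extra: dict | None = None) -> None:
    """Self-describing checkpoint: parameters + config + registry + scaling."""
    from .terms import save_registry  # local import to avoid cycle at import time

    meta = {"config": model.config.to_dict(), "seed": model.seed,
            "extra": extra or {}}
    if scaling is not None:
        meta["scaling"] = {"n_examples": scaling.n_examples,
                           "factors": scaling.factors.to_dict()}
    if registry is not None:
        meta["registry"] = [d.to_dict() for d in registry]
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, registry, scaling, extra)."""
    import pandas as pd

    from .terms import ScalingFactors, TermDescriptor

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    model = build_model(ModelConfig.from_dict(meta["config"]), meta["seed"])
    for i, p in enumerate(model.parameters()):
        p.value[...] = data[f"param_{i}"]
    registry = ([TermDescriptor.from_dict(d) for d in meta["registry"]]
                if "registry" in meta else None)
    scaling = (ScalingFactors(factors=pd.Series(meta["scaling"]["factors"]),
                              n_examples=meta["scaling"]["n_examples"])
               if "scaling" in meta else None)
    return model, registry, scaling, meta.get("extra", {})
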