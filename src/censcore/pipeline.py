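"""Convenience layer gluing the modules into end-to-end flows.

These helpers are what the command-line interface and the examples use:
loading a simulated corpus back from its on-disk formats, and scoring a
single complex from structure to decomposed affinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .cenmodel import CENModel, Prediction, predict_affinity, predict_weights
from .split import filter_affinities, read_affinity_table
from .structio import ComplexStructure, read_complex
from .terms import (ScalingFactors, TermDescriptor, apply_scaling, featurize,
                    load_registry)
from .training import TrainingExample
from .voxelize import GridConfig, voxelize

__all__ = ["SimulatedBundle", "load_simulated_examples", "score_complex"]


@dataclass
class SimulatedBundle:
    examples: list[TrainingExample]
    registry: list[TermDescriptor]
    scaling: ScalingFactors


def load_simulated_examples(datadir) -> SimulatedBundle:
    """Re-read a simulated corpus from its PDB/SDF/TSV/JSON files.

    Applies the affinity-qualifier filter, refeaturizes each structure and
    scales with the stored factors, so the result flows through exactly the
    same code paths as externally supplied data.
    """
    datadir = Path(datadir)
    registry = load_registry(datadir / "registry.json")
    scaling = ScalingFactors.from_json(datadir / "scaling.json")
    records = filter_affinities(read_affinity_table(datadir / "affinities.tsv"))
    examples = []
    for rec in records:
        receptor = datadir / "structures" / f"{rec.entry_id}_receptor.pdb"
        ligand = datadir / "structures" / f"{rec.entry_id}_ligand.sdf"
        if not receptor.exists() or not ligand.exists():
            continue
        complex_ = read_complex(receptor, ligand, entry_id=rec.entry_id)
        scaled = apply_scaling(featurize(complex_, registry), scaling)
        examples.append(TrainingExample(complex=complex_, scaled_terms=scaled,
                                        pk=rec.pk))
    return SimulatedBundle(examples=examples, registry=registry, scaling=scaling)


def score_complex(complex_: ComplexStructure, model: CENModel,
                  registry: list[TermDescriptor], scaling: ScalingFactors,
                  grid_dim: int | None = None,
                  grid_resolution: float | None = None) -> Prediction:
    """Structure -> terms -> grid -> weights -> decomposed affinity."""
    dim = grid_dim or model.config.grid_dim
    gcfg = GridConfig(dim=dim, resolution=grid_resolution or 24.0 / dim)
    scaled = apply_scaling(featurize(complex_, registry), scaling)
    weights = predict_weights(model, voxelize(complex_, gcfg))
    return predict_affinity(weights, scaled)
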