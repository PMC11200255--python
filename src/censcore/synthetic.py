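"""Desk-scale synthetic complexes with context-dependent ground truth.

Generates toy protein pockets (a jittered spherical shell of receptor atoms)
enclosing random small ligands, with element identities, hydrogen-bond
flags and partial charges chosen so that every term family is exercised.
Each complex belongs to a *context* encoded in a structural property that
the voxel grid can see: the fraction of hydrophobic carbons lining the
pocket (a polar pocket band vs a hydrophobic pocket band by default).

Ground-truth affinities are context-dependent linear functions of the scaled
terms: ``pK_e = w*_{k(e)} . t_e + noise``, where the per-context true weight
vectors ``w*_k`` agree on most terms but differ in sign on the first
electrostatic term. Because the ligand and receptor charges are drawn
independently of the pocket context, no single global linear model can
represent that sign flip, while a context-aware model can — the property the
recovery tests probe. Affinities are clipped to the plausible pK range
[0, 14], and qualifier codes are sampled so the affinity filter rules are
exercised on generated tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import AffinityRecord, Atom, ComplexStructure, assign_xs_types
from .terms import (ScalingFactors, TermDescriptor, TermVector, apply_scaling,
                    featurize_dataset, fit_scaling, named_physicochemical_terms)

__all__ = ["SyntheticSpec", "SyntheticDataset", "synthetic_registry",
           "default_true_weights", "generate_complex", "generate_dataset",
           "write_dataset_files"]


def synthetic_registry() -> list[TermDescriptor]:
    """Compact registry for desk-scale runs: the named terms plus three
    attributable atom_type_gaussian terms."""
    registry = named_physicochemical_terms()
    for pair in [("AliphaticCarbonXSHydrophobe", "AliphaticCarbonXSHydrophobe"),
                 ("NitrogenXSDonor", "OxygenXSAcceptor"),
                 ("AliphaticCarbonXSHydrophobe", "OxygenXSDonorAcceptor")]:
        registry.append(TermDescriptor("atom_type_gaussian",
                                       {"o": 0.0, "w": 1.0, "c": 8.0},
                                       type_pair=pair))
    return registry


def default_true_weights(registry: list[TermDescriptor],
                         n_contexts: int = 2) -> np.ndarray:
    """Per-context true weight matrix (K x terms).

    Most weights are shared across contexts; the first electrostatic term
    flips sign between contexts (favorable in the polar-pocket context,
    unfavorable in the hydrophobic-pocket context), which is the context
    signal the recovery tests require a model to exploit.
    """
    shared = {
        "gauss(o=0,_w=0.5,_c=8)": 1.0,
        "gauss(o=3,_w=2,_c=8)": 1.0,
        "repulsion(o=0,_c=8)": -1.0,
        "hydrophobic(g=0.5,_b=1.5,_c=8)": 1.0,
        "non_dir_h_bond(g=-0.7,_b=0,_c=8)": 1.5,
        "electrostatic(i=2,_^=100,_c=8)": -0.5,
        "num_tors_div": -0.5,
        "num_hydrophobic_atoms": 1.0,
        "num_heavy_atoms": 2.0,
        "ligand_length": 2.0,
    }
    flipped = "electrostatic(i=1,_^=100,_c=8)"
    flip_magnitude = 6.0
    W = np.zeros((n_contexts, len(registry)))
    for j, desc in enumerate(registry):
        if desc.name == flipped:
            for k in range(n_contexts):
                W[k, j] = flip_magnitude * (-1.0 if k % 2 == 0 else 1.0)
        elif desc.family == "atom_type_gaussian":
            W[:, j] = 0.5
        else:
            W[:, j] = shared.get(desc.name, 0.0)
    return W


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic corpus."""

    n_complexes: int = 600
    receptor_atoms: tuple[int, int] = (40, 60)
    ligand_atoms: tuple[int, int] = (8, 16)
    pocket_radius: float = 6.0
    n_contexts: int = 2
    hydrophobic_bands: tuple = ((0.15, 0.35), (0.65, 0.85))
    noise_std: float = 0.3      # pK units
    seed: int = 0
    registry: list[TermDescriptor] = field(default_factory=synthetic_registry)
    true_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.n_contexts < 1 or len(self.hydrophobic_bands) < self.n_contexts:
            raise ValueError("need a hydrophobic band per context")
        if self.noise_std < 0:
            raise ValueError("noise std must be >= 0")
        if self.ligand_atoms[0] < 1:
            raise ValueError("ligands must have at least one atom")
        if self.receptor_atoms[0] < 4:
            raise ValueError("receptors need at least 4 atoms")
        if self.true_weights is None:
            self.true_weights = default_true_weights(self.registry, self.n_contexts)
        self.true_weights = np.asarray(self.true_weights, float)
        if self.true_weights.shape != (self.n_contexts, len(self.registry)):
            raise ValueError("true_weights shape must be (n_contexts, n_terms)")


@dataclass
class SyntheticDataset:
    complexes: list[ComplexStructure]
    records: list[AffinityRecord]
    cluster_table: dict[str, list]
    context_of_entry: dict[str, int]
    registry: list[TermDescriptor]
    true_weights: np.ndarray
    scaling: ScalingFactors
    scaled_terms: pd.DataFrame     # entries x terms, scaled
    pk_of_entry: dict[str, float]

    def scaled_vector(self, entry_id: str) -> TermVector:
        row = self.scaled_terms.loc[entry_id]
        return TermVector(entry_id=entry_id, names=list(row.index),
                          values=row.to_numpy(), scaled=True)


# ---------------------------------------------------------------------------
# Structure generation

_POLAR_CHOICES = (
    # (element, n_bonded_h, bonded_elements) -> donor/acceptor variety
    ("N", 2, ("C",)),      # NitrogenXSDonorAcceptor
    ("N", 3, ("C",)),      # NitrogenXSDonor (ammonium-like, no lone pair)
    ("N", 0, ("C", "C")),  # NitrogenXSAcceptor
    ("O", 1, ("C",)),      # OxygenXSDonorAcceptor
    ("O", 0, ("C",)),      # OxygenXSAcceptor
)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_complex(spec: SyntheticSpec, rng: np.random.Generator,
                     context: int | None = None,
                     entry_id: str = "synthetic") -> ComplexStructure:
    """One toy pocket/ligand complex, reproducible from the generator state.

    The receptor is a jittered spherical shell around the origin whose
    hydrophobic-carbon fraction is drawn from the context's band; the ligand
    occupies the interior. Two contact motifs are placed deterministically —
    a donor/acceptor pair in hydrogen-bond range and a hydrophobic pair in
    steric-clash range — so the h-bond, hydrophobic and repulsion families
    are exercised in (nearly) every complex.
    """
    if context is None:
        context = int(rng.integers(spec.n_contexts))
    lo, hi = spec.hydrophobic_bands[context]
    frac_phobic = rng.uniform(lo, hi)
    n_rec = int(rng.integers(spec.receptor_atoms[0], spec.receptor_atoms[1] + 1))
    n_lig = int(rng.integers(spec.ligand_atoms[0], spec.ligand_atoms[1] + 1))
    R = spec.pocket_radius

    atoms: list[Atom] = []
    idx = 0

    def add(element, pos, n_h, bonded, charge):
        nonlocal idx
        atoms.append(Atom(index=idx, element=element, coords=np.asarray(pos, float),
                          partial_charge=float(charge), n_bonded_h=int(n_h),
                          bonded_elements=tuple(bonded),
                          resname="REC" if idx < n_rec else "LIG"))
        idx += 1

    # receptor shell; charges independent of pocket composition by design
    hb_dir = _random_unit(rng)
    clash_dir = _random_unit(rng)
    for n in range(n_rec):
        if n == 0:  # hydrogen-bond motif wall atom (pure donor nitrogen)
            pos = hb_dir * (R - 1.2)
            add("N", pos, 3, ("C",), rng.normal(0, 0.15))
            continue
        if n == 1:  # steric-clash motif wall atom (hydrophobic carbon)
            pos = clash_dir * (R - 1.4)
            add("C", pos, 2, ("C", "C"), rng.normal(0, 0.15))
            continue
        pos = _random_unit(rng) * rng.uniform(R - 0.8, R + 0.8)
        if rng.uniform() < frac_phobic:
            add("C", pos, 2, ("C", "C"), rng.normal(0, 0.15))
        else:
            el, n_h, bonded = _POLAR_CHOICES[rng.integers(len(_POLAR_CHOICES))]
            add(el, pos, n_h, bonded, rng.normal(0, 0.15))
    n_rec_actual = idx

    # ligand: interior ball with minimum separation
    positions = []
    # motif partners: acceptor oxygen facing the wall donor, hydrophobic
    # carbon clashing with the wall carbon
    positions.append(hb_dir * (R - 1.2 - rng.uniform(2.6, 3.2)))
    positions.append(clash_dir * (R - 1.4 - rng.uniform(2.6, 3.4)))
    tries = 0
    while len(positions) < n_lig and tries < 2000:
        tries += 1
        cand = _random_unit(rng) * rng.uniform(0, 2.8) ** 1.0
        if all(np.linalg.norm(cand - p) >= 1.1 for p in positions):
            positions.append(cand)
    for n, pos in enumerate(positions):
        charge = rng.normal(0, 0.25)
        if n == 0:
            add("O", pos, 0, ("C",), charge)     # acceptor
        elif n == 1:
            add("C", pos, 3, ("C",), charge)     # hydrophobe
        elif rng.uniform() < 0.5:
            add("C", pos, 2, ("C", "C"), charge)
        else:
            el, n_h, bonded = _POLAR_CHOICES[rng.integers(len(_POLAR_CHOICES))]
            add(el, pos, n_h, bonded, charge)

    complex_ = ComplexStructure(
        entry_id=entry_id,
        receptor_atoms=atoms[:n_rec_actual],
        ligand_atoms=atoms[n_rec_actual:],
        ligand_rotatable_bonds=int(rng.integers(0, 9)),
        metadata={"context": context, "hydrophobic_fraction": frac_phobic,
                  "synthetic": True},
    )
    return assign_xs_types(complex_)


# ---------------------------------------------------------------------------
# Dataset generation

_QUALIFIER_CODES = ("=", "=", "=", "=", "=", "=", "=", "=", "=", "=", "=",
                    "=", "~", ">", "<")


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Complexes + affinity records + cluster table with known ground truth.

    ``pK_e = w*_{k(e)} . t_e + Normal(0, noise_std)``, clipped to [0, 14],
    where ``t_e`` are the max-abs-scaled terms over the whole corpus.
    Cluster ids are context-linked with jitter (five synthetic sequence
    clusters per context) so clustered splits are nontrivial, and qualifier
    codes are sampled so affinity filtering drops a known subset.
    """
    rng = np.random.default_rng(spec.seed)
    contexts = rng.integers(spec.n_contexts, size=spec.n_complexes)
    complexes = [generate_complex(spec, rng, context=int(k),
                                  entry_id=f"synth-{n:04d}")
                 for n, k in enumerate(contexts)]
    raw = featurize_dataset(complexes, spec.registry)
    scaling = fit_scaling(raw)
    scaled = apply_scaling(raw, scaling)

    noise = rng.normal(0, spec.noise_std, size=spec.n_complexes)
    W = spec.true_weights
    pk = np.clip((scaled.to_numpy() * W[contexts]).sum(axis=1) + noise, 0.0, 14.0)

    records, cluster_table, context_of, pk_of = [], {}, {}, {}
    measures = ("Kd", "Ki", "IC50")
    for n, c in enumerate(complexes):
        qualifier = _QUALIFIER_CODES[rng.integers(len(_QUALIFIER_CODES))]
        records.append(AffinityRecord(
            entry_id=c.entry_id,
            measure=measures[rng.integers(3)],
            qualifier=qualifier,
            value=float(10.0 ** (-pk[n])) if pk[n] > 0 else 1.0,
        ))
        cluster_table[c.entry_id] = [int(contexts[n]) * 5 + int(rng.integers(5))]
        context_of[c.entry_id] = int(contexts[n])
        pk_of[c.entry_id] = float(pk[n])
    return SyntheticDataset(complexes=complexes, records=records,
                            cluster_table=cluster_table,
                            context_of_entry=context_of,
                            registry=spec.registry, true_weights=W,
                            scaling=scaling, scaled_terms=scaled,
                            pk_of_entry=pk_of)


# ---------------------------------------------------------------------------
# File export (so synthetic data flows through the same formats as real data)


def _write_pdb(atoms, path):
    lines = []
    for n, a in enumerate(atoms, start=1):
        lines.append(
            f"ATOM  {n:>5} {a.element:<4}{'REC':>4} A{1:>4}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_sdf(complex_, path):
    lig = complex_.ligand_atoms
    lines = [complex_.entry_id, "  censcore synthetic", ""]
    lines.append(f"{len(lig):>3}  0  0  0  0  0  0  0  0  0999 V2000")
    for a in lig:
        lines.append(f"{a.coords[0]:>10.4f}{a.coords[1]:>10.4f}"
                     f"{a.coords[2]:>10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    lines.append("M  END")
    lines.append(">  <atom.dprop.PartialCharge>")
    lines.append(" ".join(f"{a.partial_charge:.6f}" for a in lig))
    lines.append("")
    lines.append(">  <rotatable_bonds>")
    lines.append(str(complex_.ligand_rotatable_bonds))
    lines.append("")
    lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset_files(dataset: SyntheticDataset, outdir) -> dict:
    """Write receptor PDBs, ligand SDFs, affinity and cluster TSVs.

    Returns a manifest dict mapping entry ids to the written file paths.
    Note the SDF carries no bond block, so bond-derived typing of re-read
    ligands is approximate; the tables and geometry round-trip exactly.
    """
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    manifest = {}
    for c in dataset.complexes:
        rec = outdir / "structures" / f"{c.entry_id}_receptor.pdb"
        lig = outdir / "structures" / f"{c.entry_id}_ligand.sdf"
        _write_pdb(c.receptor_atoms, rec)
        _write_sdf(c, lig)
        manifest[c.entry_id] = {"receptor": str(rec), "ligand": str(lig)}
    aff = pd.DataFrame(
        [{"entry_id": r.entry_id, "measure": r.measure, "qualifier": r.qualifier,
          "value": r.value / 1e-9, "unit": "nM"} for r in dataset.records])
    aff.to_csv(outdir / "affinities.tsv", sep="\t", index=False)
    clus = pd.DataFrame(
        [{"entry_id": e, "cluster_id": cs[0]}
         for e, cs in dataset.cluster_table.items()])
    clus.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    return manifest
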