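"""Molecular structure I/O and extended (XS) atom typing.

Reads receptor structures (PDB, or the PDBQT charge dialect when partial
charges are embedded) and ligand structures (SDF or MOL2) into a uniform
:class:`ComplexStructure`, assigns Vina-style XS interaction types
(hydrophobic/non-hydrophobic carbon, donor/acceptor nitrogen and oxygen
variants, halogens, metals), and writes per-atom attribution values back out
as PDB B-factors for visualization.

Inputs are assumed preprocessed (hydrogens added, protonation states
assigned); water molecules are stripped on read. When no partial charges are
present in the input, charges are zero-filled and flagged in the complex
metadata, so charge-dependent terms evaluate to zero rather than failing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "ComplexStructure",
    "AffinityRecord",
    "StructureFormatError",
    "xs_type_table",
    "read_complex",
    "assign_xs_types",
    "write_attribution_pdb",
]

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "DOD", "H2O"}

_XS_TABLE = None


def xs_type_table() -> dict:
    """Return the packaged XS-type registry (radii, flags, canonical pair types)."""
    global _XS_TABLE
    if _XS_TABLE is None:
        with resources.files("censcore.data").joinpath("xs_types.json").open() as fh:
            _XS_TABLE = json.load(fh)
    return _XS_TABLE


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or violates a contract."""


@dataclass
class Atom:
    """A typed, charged 3D atom.

    ``bonded_elements``, ``n_bonded_h``, ``is_aromatic`` and ``formal_charge``
    carry the bonding context needed for XS typing, so typing is a pure
    function of the atom record (readers and the synthetic generator both
    populate them).
    """

    index: int
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    xs_type: str | None = None
    is_hydrogen: bool = False
    vdw_radius: float = 0.0
    bonded_elements: tuple[str, ...] = ()
    n_bonded_h: int = 0
    is_aromatic: bool = False
    formal_charge: int = 0
    resname: str = "UNK"
    name: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return not self.is_hydrogen

    def _flag(self, key: str) -> bool:
        if self.xs_type is None:
            return False
        return xs_type_table()["types"][self.xs_type][key]

    @property
    def is_hydrophobic(self) -> bool:
        return self._flag("hydrophobic")

    @property
    def is_donor(self) -> bool:
        return self._flag("donor")

    @property
    def is_acceptor(self) -> bool:
        return self._flag("acceptor")


@dataclass
class ComplexStructure:
    """Receptor and ligand atoms of one protein/ligand complex."""

    entry_id: str
    receptor_atoms: list[Atom]
    ligand_atoms: list[Atom]
    ligand_rotatable_bonds: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ligand_rotatable_bonds < 0:
            raise ValueError("rotatable-bond count must be >= 0")
        rec = {a.index for a in self.receptor_atoms}
        lig = {a.index for a in self.ligand_atoms}
        if rec & lig:
            raise ValueError("receptor and ligand atom index spaces overlap")

    def receptor_heavy(self) -> list[Atom]:
        return [a for a in self.receptor_atoms if a.is_heavy]

    def ligand_heavy(self) -> list[Atom]:
        return [a for a in self.ligand_atoms if a.is_heavy]

    @property
    def all_atoms(self) -> list[Atom]:
        return self.receptor_atoms + self.ligand_atoms

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray) -> "ComplexStructure":
        """Rigidly rotate about ``center`` then translate; returns a copy."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)

        def _move(atoms):
            return [replace(a, coords=rotation @ (a.coords - center) + center + translation)
                    for a in atoms]

        return replace(self, receptor_atoms=_move(self.receptor_atoms),
                       ligand_atoms=_move(self.ligand_atoms))


@dataclass(frozen=True)
class AffinityRecord:
    """One experimental affinity annotation (Kd, Ki or IC50)."""

    entry_id: str
    measure: str
    qualifier: str
    value: float  # molar

    def __post_init__(self):
        if self.measure not in {"Kd", "Ki", "IC50"}:
            raise ValueError(f"{self.entry_id}: unknown measure {self.measure!r}")
        if self.qualifier not in {"=", "~", ">", "<"}:
            raise ValueError(f"{self.entry_id}: unknown qualifier {self.qualifier!r}")
        if not (self.value > 0 and np.isfinite(self.value)):
            raise ValueError(f"{self.entry_id}: affinity value must be positive")

    @property
    def pk(self) -> float:
        """-log10 of the molar value (pKd / pKi / pIC50)."""
        return float(-np.log10(self.value))


# ---------------------------------------------------------------------------
# XS typing


def _type_heavy_atom(atom: Atom) -> str:
    table = xs_type_table()
    el = atom.element.upper()
    if el in table["element_map"]:
        # sulfur bound to nothing heavier than one neighbor acts as an acceptor
        if el == "S" and len(atom.bonded_elements) + atom.n_bonded_h <= 1:
            return "SulfurAcceptor"
        return table["element_map"][el]
    if el == "C":
        heteros = any(b.upper() not in {"C", "H"} for b in atom.bonded_elements)
        ring = "Aromatic" if atom.is_aromatic else "Aliphatic"
        phob = "NonHydrophobe" if heteros else "Hydrophobe"
        return f"{ring}CarbonXS{phob}"
    if el == "N":
        donor = atom.n_bonded_h > 0
        # a lone pair remains when fewer than four connections and no + charge
        n_conn = len(atom.bonded_elements) + atom.n_bonded_h
        acceptor = n_conn < 4 and atom.formal_charge <= 0
        if donor and acceptor:
            return "NitrogenXSDonorAcceptor"
        if donor:
            return "NitrogenXSDonor"
        if acceptor:
            return "NitrogenXSAcceptor"
        return "Nitrogen"
    if el == "O":
        donor = atom.n_bonded_h > 0
        acceptor = atom.formal_charge <= 0
        if donor and acceptor:
            return "OxygenXSDonorAcceptor"
        if donor:
            return "OxygenXSDonor"
        if acceptor:
            return "OxygenXSAcceptor"
        return "Oxygen"
    return "GenericMetal"


def assign_xs_types(complex_: ComplexStructure) -> ComplexStructure:
    """Assign an XS interaction type and vdW radius to every atom.

    Deterministic and idempotent: types depend only on element, bonding
    context, aromaticity and formal charge. Unknown elements are typed as
    GenericMetal and recorded in ``metadata['generic_typed']``.
    """
    table = xs_type_table()
    generic: list[int] = []
    for atom in complex_.all_atoms:
        if atom.is_hydrogen:
            atom.xs_type = "PolarHydrogen" if atom.bonded_elements and all(
                b.upper() in {"N", "O", "S"} for b in atom.bonded_elements) else "Hydrogen"
        else:
            atom.xs_type = _type_heavy_atom(atom)
            if atom.xs_type == "GenericMetal" and atom.element.upper() not in table["element_map"]:
                generic.append(atom.index)
        atom.vdw_radius = table["types"][atom.xs_type]["vdw_radius"]
    if generic:
        complex_.metadata["generic_typed"] = generic
    return complex_


# ---------------------------------------------------------------------------
# Readers


def _atoms_from_rdkit(mol, index_offset: int, charge_prop: str | None = None,
                      skip_waters: bool = True) -> list[Atom]:
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    idx = index_offset
    for rd_atom in mol.GetAtoms():
        info = rd_atom.GetPDBResidueInfo()
        resname = info.GetResidueName().strip() if info is not None else "UNK"
        name = info.GetName().strip() if info is not None else rd_atom.GetSymbol()
        if skip_waters and resname in WATER_RESNAMES:
            continue
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        charge = 0.0
        if charge_prop is not None and rd_atom.HasProp(charge_prop):
            charge = rd_atom.GetDoubleProp(charge_prop)
        neighbors = [n.GetSymbol() for n in rd_atom.GetNeighbors()]
        bonded_heavy = tuple(s for s in neighbors if s != "H")
        n_h = sum(1 for s in neighbors if s == "H") + rd_atom.GetNumImplicitHs()
        atoms.append(Atom(
            index=idx,
            element=rd_atom.GetSymbol(),
            coords=np.array([pos.x, pos.y, pos.z]),
            partial_charge=float(charge),
            is_hydrogen=rd_atom.GetAtomicNum() == 1,
            bonded_elements=bonded_heavy,
            n_bonded_h=n_h,
            is_aromatic=rd_atom.GetIsAromatic(),
            formal_charge=rd_atom.GetFormalCharge(),
            resname=resname,
            name=name,
        ))
        idx += 1
    return atoms


def _read_pdb_receptor(path: Path) -> tuple[list[Atom], str]:
    from rdkit import Chem

    mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False,
                              proximityBonding=True)
    if mol is None:
        raise StructureFormatError(f"unparseable PDB file: {path}")
    try:
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
                         | Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    except Exception:
        pass  # aromaticity perception is best-effort on raw PDB records
    return _atoms_from_rdkit(mol, 0), "absent-zero-filled"


def _read_pdbqt_receptor(path: Path) -> tuple[list[Atom], str]:
    """Minimal reader for the PDBQT charge dialect (coords + partial charge).

    PDBQT appends the Gasteiger charge and AutoDock type after the standard
    ATOM columns; no installed reader handles it, so the fixed columns are
    parsed directly. Bonding context is unavailable, so carbons are typed from
    the AutoDock type field (A = aromatic) and polarity is inferred later from
    geometry-free defaults.
    """
    atoms: list[Atom] = []
    idx = 0
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            resname = line[17:20].strip()
            if resname in WATER_RESNAMES:
                continue
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            charge = float(line[66:76])
            ad_type = line[77:79].strip() or line[12:16].strip()[:1]
        except (ValueError, IndexError) as exc:
            raise StructureFormatError(f"{path}: bad PDBQT record at line {ln}") from exc
        element = {"A": "C", "OA": "O", "NA": "N", "SA": "S", "HD": "H"}.get(
            ad_type, ad_type[:1].upper() + ad_type[1:].lower())
        atoms.append(Atom(
            index=idx, element=element, coords=np.array([x, y, z]),
            partial_charge=charge, is_hydrogen=element == "H",
            is_aromatic=ad_type == "A", resname=resname,
            name=line[12:16].strip(),
        ))
        idx += 1
    if not atoms:
        raise StructureFormatError(f"{path}: no ATOM/HETATM records")
    return atoms, "pdbqt"


def _read_ligand(path: Path, index_offset: int) -> tuple[list[Atom], int, str]:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next((m for m in supplier if m is not None), None)
        charge_prop, source = "PartialCharge", "sdf-property"
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
        charge_prop, source = "_TriposPartialCharge", "mol2"
    else:
        raise StructureFormatError(f"unsupported ligand format: {path.suffix}")
    if mol is None:
        raise StructureFormatError(f"unparseable ligand file: {path}")
    atoms = _atoms_from_rdkit(mol, index_offset, charge_prop=charge_prop,
                              skip_waters=False)
    if not any(a.is_heavy for a in atoms):
        raise StructureFormatError(f"{path}: ligand has no heavy atoms")
    if not any(a.partial_charge != 0.0 for a in atoms):
        source = "absent-zero-filled"
    if mol.HasProp("rotatable_bonds"):  # explicit annotation wins over topology
        n_rot = int(mol.GetProp("rotatable_bonds"))
    else:
        n_rot = int(Descriptors.NumRotatableBonds(mol))
    return atoms, n_rot, source


def read_complex(receptor_path, ligand_path, entry_id: str | None = None) -> ComplexStructure:
    """Read a receptor (PDB/PDBQT) and a ligand (SDF/MOL2) into one complex.

    Waters are excluded; XS types are assigned; charge provenance is recorded
    in ``metadata['receptor_charge_source'|'ligand_charge_source']``
    (``absent-zero-filled`` when the file carried none).
    """
    receptor_path, ligand_path = Path(receptor_path), Path(ligand_path)
    if receptor_path.suffix.lower() == ".pdbqt":
        rec_atoms, rec_source = _read_pdbqt_receptor(receptor_path)
    else:
        rec_atoms, rec_source = _read_pdb_receptor(receptor_path)
    lig_atoms, n_rot, lig_source = _read_ligand(ligand_path, len(rec_atoms))
    complex_ = ComplexStructure(
        entry_id=entry_id or receptor_path.stem,
        receptor_atoms=rec_atoms,
        ligand_atoms=lig_atoms,
        ligand_rotatable_bonds=n_rot,
        metadata={
            "receptor_path": str(receptor_path),
            "ligand_path": str(ligand_path),
            "receptor_charge_source": rec_source,
            "ligand_charge_source": lig_source,
        },
    )
    return assign_xs_types(complex_)


# ---------------------------------------------------------------------------
# Attribution writer


def write_attribution_pdb(complex_: ComplexStructure, attribution, path,
                          display_filter: bool = False,
                          display_threshold: float = 0.025,
                          clamp: float = 0.15) -> None:
    """Write the complex as PDB with attribution values in the B-factor column.

    Values are clamped to ``[-clamp, +clamp]`` (the red/white/blue color
    range); with ``display_filter`` enabled, values with magnitude at or below
    ``display_threshold`` are written as zero so only salient contacts color.
    """
    per_atom = attribution.per_atom if hasattr(attribution, "per_atom") else dict(attribution)
    lines = []
    serial = 1
    for group, chain in ((complex_.receptor_atoms, "A"), (complex_.ligand_atoms, "B")):
        for atom in group:
            value = float(per_atom.get(atom.index, 0.0))
            value = max(-clamp, min(clamp, value))
            if display_filter and abs(value) <= display_threshold:
                value = 0.0
            name = (atom.name or atom.element)[:4]
            resname = (atom.resname or "UNK")[:3]
            lines.append(
                f"HETATM{serial:>5} {name:<4}{resname:>4} {chain}{1:>4}    "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.00:6.2f}{value:6.2f}          {atom.element:>2}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
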