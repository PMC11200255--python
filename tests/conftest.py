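import numpy as np
import pytest

from censcore.structio import Atom, ComplexStructure, assign_xs_types


def make_atom(index, element, coords, charge=0.0, n_h=0, bonded=("C",),
              aromatic=False, formal=0):
    return Atom(index=index, element=element, coords=np.asarray(coords, float),
                partial_charge=charge, n_bonded_h=n_h,
                bonded_elements=tuple(bonded), is_aromatic=aromatic,
                formal_charge=formal, is_hydrogen=element == "H")


def make_complex(receptor_specs, ligand_specs, entry_id="toy", n_rot=0):
    """Build a typed complex from (element, coords, kwargs) tuples."""
    atoms, idx = [], 0
    rec = []
    for spec in receptor_specs:
        element, coords = spec[0], spec[1]
        kwargs = spec[2] if len(spec) > 2 else {}
        rec.append(make_atom(idx, element, coords, **kwargs))
        idx += 1
    lig = []
    for spec in ligand_specs:
        element, coords = spec[0], spec[1]
        kwargs = spec[2] if len(spec) > 2 else {}
        lig.append(make_atom(idx, element, coords, **kwargs))
        idx += 1
    return assign_xs_types(ComplexStructure(
        entry_id=entry_id, receptor_atoms=rec, ligand_atoms=lig,
        ligand_rotatable_bonds=n_rot))


def random_complex(rng, n_rec=30, n_lig=10):
    """A randomized typed toy complex exercising charges and all flag kinds."""
    elements = ["C", "C", "C", "N", "O", "O", "S", "F", "Cl"]
    variants = {
        "C": [{"n_h": 3, "bonded": ("C",)}, {"n_h": 0, "bonded": ("C", "O")},
              {"n_h": 1, "bonded": ("C", "C"), "aromatic": True}],
        "N": [{"n_h": 2, "bonded": ("C",)}, {"n_h": 0, "bonded": ("C", "C")},
              {"n_h": 3, "bonded": ("C",)}],
        "O": [{"n_h": 1, "bonded": ("C",)}, {"n_h": 0, "bonded": ("C",)}],
        "S": [{"n_h": 0, "bonded": ("C", "C")}],
        "F": [{"n_h": 0, "bonded": ("C",)}],
        "Cl": [{"n_h": 0, "bonded": ("C",)}],
    }

    def specs(n, scale, offset):
        out = []
        for _ in range(n):
            el = elements[rng.integers(len(elements))]
            kw = dict(variants[el][rng.integers(len(variants[el]))])
            kw["charge"] = float(rng.normal(0, 0.3))
            out.append((el, rng.normal(offset, scale, 3), kw))
        return out

    return make_complex(specs(n_rec, 3.0, 0.0), specs(n_lig, 1.5, 2.0),
                        entry_id="random", n_rot=int(rng.integers(0, 9)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_complex():
    """One receptor N-donor + hydrophobic C, one ligand O-acceptor + C."""
    return make_complex(
        [("N", (0.0, 0.0, 0.0), {"n_h": 3, "bonded": ("C",), "charge": 0.3}),
         ("C", (4.0, 0.0, 0.0), {"n_h": 3, "bonded": ("C",), "charge": -0.1})],
        [("O", (3.0, 0.0, 0.0), {"n_h": 0, "bonded": ("C",), "charge": -0.4}),
         ("C", (3.0, 1.5, 0.0), {"n_h": 3, "bonded": ("C",), "charge": 0.05})],
        n_rot=2)
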