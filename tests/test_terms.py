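"""Term calculators against brute-force oracles, plus scaling and filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from censcore.structio import xs_type_table
from censcore.terms import (ScalingFactors, TermDescriptor, apply_scaling,
                            default_registry, enumerate_pairs, eval_term,
                            featurize, featurize_dataset, filter_sparse_terms,
                            fit_scaling, load_registry, save_registry)

from conftest import make_complex, random_complex


# ---------------------------------------------------------------------------
# Independent oracle: plain double loop over all heavy-atom pairs.

def brute_force_term(desc, complex_):
    lig = complex_.ligand_heavy()
    if desc.family == "count":
        if desc.count_kind == "num_tors_div":
            return complex_.ligand_rotatable_bonds / desc.params.get("divisor", 5.0)
        if desc.count_kind == "num_hydrophobic_atoms":
            return sum(a.is_hydrophobic for a in lig)
        if desc.count_kind == "num_heavy_atoms":
            return len(lig)
        if desc.count_kind == "ligand_length":
            best = 0.0
            for a in lig:
                for b in lig:
                    best = max(best, float(np.linalg.norm(a.coords - b.coords)))
            return best
    p = desc.params
    total = 0.0
    for ra in complex_.receptor_heavy():
        for la in lig:
            d = float(np.linalg.norm(ra.coords - la.coords))
            if d > p["c"]:
                continue
            ds = d - (ra.vdw_radius + la.vdw_radius)
            if desc.family == "gauss":
                total += math.exp(-(((ds - p["o"]) / p["w"]) ** 2))
            elif desc.family == "repulsion":
                if ds < p["o"]:
                    total += (ds - p["o"]) ** 2
            elif desc.family == "hydrophobic":
                if ra.is_hydrophobic and la.is_hydrophobic:
                    total += min(1.0, max(0.0, (p["b"] - ds) / (p["b"] - p["g"])))
            elif desc.family == "non_dir_h_bond":
                if (ra.is_donor and la.is_acceptor) or (ra.is_acceptor and la.is_donor):
                    total += min(1.0, max(0.0, (p["b"] - ds) / (p["b"] - p["g"])))
            elif desc.family == "electrostatic":
                v = ra.partial_charge * la.partial_charge / d ** p["i"]
                total += max(-p["cap"], min(p["cap"], v))
            elif desc.family == "atom_type_gaussian":
                if {ra.xs_type, la.xs_type} == set(desc.type_pair):
                    o, w = p.get("o", 0.0), p.get("w", 1.0)
                    total += math.exp(-(((ds - o) / w) ** 2))
    return total


class TestEnumeratePairs:
    def test_single_pair_geometry(self):
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 5), {"n_h": 4, "bonded": ()})])
        pairs = enumerate_pairs(c, cutoff=8.0)
        assert len(pairs) == 1
        assert pairs[0].d == pytest.approx(5.0)
        assert pairs[0].d0 == pytest.approx(3.8)

    def test_cutoff_excludes(self):
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 5), {"n_h": 4, "bonded": ()})])
        assert enumerate_pairs(c, cutoff=4.0) == []

    def test_matches_all_pairs_oracle(self, rng):
        c = random_complex(rng, n_rec=50, n_lig=20)
        pairs = {(p.receptor_atom, p.ligand_atom) for p in enumerate_pairs(c, 8.0)}
        expected = set()
        for ra in c.receptor_heavy():
            for la in c.ligand_heavy():
                if np.linalg.norm(ra.coords - la.coords) <= 8.0:
                    expected.add((ra.index, la.index))
        assert pairs == expected


class TestEvalTerm:
    def test_electrostatic_hand_value(self):
        c = make_complex(
            [("C", (0, 0, 0), {"n_h": 4, "bonded": (), "charge": 0.5})],
            [("C", (0, 0, 2), {"n_h": 4, "bonded": (), "charge": -0.5})])
        desc = TermDescriptor("electrostatic", {"i": 1, "cap": 100.0, "c": 8.0})
        assert eval_term(desc, c) == pytest.approx(-0.125)

    def test_electrostatic_cap(self):
        # q1*q2/d^2 = 400 -> capped at 100
        c = make_complex(
            [("C", (0, 0, 0), {"n_h": 4, "bonded": (), "charge": 2.0})],
            [("C", (0, 0, 0.1), {"n_h": 4, "bonded": (), "charge": 2.0})])
        desc = TermDescriptor("electrostatic", {"i": 2, "cap": 100.0, "c": 8.0})
        assert eval_term(desc, c) == pytest.approx(100.0)

    def test_atom_type_gaussian_unity_at_contact(self):
        # pair exactly at summed radii: ds = 0 -> g = exp(0) = 1
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 3.8), {"n_h": 4, "bonded": ()})])
        desc = TermDescriptor(
            "atom_type_gaussian", {"o": 0.0, "w": 1.0, "c": 8.0},
            type_pair=("AliphaticCarbonXSHydrophobe", "AliphaticCarbonXSHydrophobe"))
        assert eval_term(desc, c) == pytest.approx(1.0)

    def test_hydrophobic_ramp_midpoint(self):
        # ds = 1.0 inside the g=0.5..b=1.5 ramp -> 0.5
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 4.8), {"n_h": 4, "bonded": ()})])
        desc = TermDescriptor("hydrophobic", {"g": 0.5, "b": 1.5, "c": 8.0})
        assert eval_term(desc, c) == pytest.approx(0.5)

    def test_hydrophobic_count(self):
        lig = [("C", (k, 0, 2.5), {"n_h": 4, "bonded": ()}) for k in range(7)]
        lig += [("O", (0, 2, 2.5), {"n_h": 0, "bonded": ("C",)})]
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})], lig)
        desc = TermDescriptor("count", count_kind="num_hydrophobic_atoms")
        assert eval_term(desc, c) == 7

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            TermDescriptor("solvation", {"c": 8.0})


class TestOracleEquivalence:
    """Every term family matches the brute-force all-pairs loop."""

    def test_all_families_on_randomized_complexes(self, rng):
        registry = [
            TermDescriptor("gauss", {"o": 0.0, "w": 0.5, "c": 8.0}),
            TermDescriptor("gauss", {"o": 3.0, "w": 2.0, "c": 8.0}),
            TermDescriptor("repulsion", {"o": 0.0, "c": 8.0}),
            TermDescriptor("hydrophobic", {"g": 0.5, "b": 1.5, "c": 8.0}),
            TermDescriptor("non_dir_h_bond", {"g": -0.7, "b": 0.0, "c": 8.0}),
            TermDescriptor("electrostatic", {"i": 1, "cap": 100.0, "c": 8.0}),
            TermDescriptor("electrostatic", {"i": 2, "cap": 100.0, "c": 8.0}),
            TermDescriptor("count", count_kind="num_tors_div",
                           params={"divisor": 5.0}),
            TermDescriptor("count", count_kind="num_hydrophobic_atoms"),
            TermDescriptor("count", count_kind="num_heavy_atoms"),
            TermDescriptor("count", count_kind="ligand_length"),
            TermDescriptor("atom_type_gaussian", {"o": 0.0, "w": 1.0, "c": 8.0},
                           type_pair=("AliphaticCarbonXSHydrophobe",
                                      "OxygenXSDonorAcceptor")),
            TermDescriptor("atom_type_gaussian", {"o": 0.0, "w": 1.0, "c": 8.0},
                           type_pair=("NitrogenXSAcceptor", "NitrogenXSAcceptor")),
        ]
        for _ in range(50):
            c = random_complex(rng, n_rec=25, n_lig=8)
            tv = featurize(c, registry)
            for desc, got in zip(registry, tv.values):
                expected = brute_force_term(desc, c)
                assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), desc.name

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        c = random_complex(rng, n_rec=20, n_lig=8)
        registry = default_registry()
        before = featurize(c, registry).values
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = c.transformed(rot, np.array([3.0, -2.0, 1.0]), np.zeros(3))
        after = featurize(moved, registry).values
        np.testing.assert_allclose(after, before, rtol=1e-9, atol=1e-12)

    def test_order_equivariance(self, rng):
        c = random_complex(rng)
        registry = default_registry()[:20]
        base = featurize(c, registry)
        perm = rng.permutation(len(registry))
        shuffled = featurize(c, [registry[i] for i in perm])
        np.testing.assert_allclose(shuffled.values, base.values[perm])


class TestRegistry:
    def test_default_registry_has_325_steric_candidates(self):
        registry = default_registry()
        atg = [d for d in registry if d.family == "atom_type_gaussian"]
        n = len(xs_type_table()["pair_types"])
        assert len(atg) == n * (n + 1) // 2 == 325

    def test_registry_json_round_trip(self, tmp_path):
        registry = default_registry()[:30]
        save_registry(registry, tmp_path / "reg.json")
        loaded = load_registry(tmp_path / "reg.json")
        assert [d.name for d in loaded] == [d.name for d in registry]


class TestSparsityFilter:
    def _matrix(self, frac_nonzero, n=200):
        atg = TermDescriptor("atom_type_gaussian", {"o": 0, "w": 1, "c": 8},
                             type_pair=("Sulfur", "Sulfur"))
        named = TermDescriptor("gauss", {"o": 0.0, "w": 0.5, "c": 8.0})
        col = np.zeros(n)
        col[:int(round(frac_nonzero * n))] = 0.7
        matrix = pd.DataFrame({named.name: np.zeros(n), atg.name: col})
        return matrix, [named, atg]

    def test_sparse_steric_dropped(self):
        matrix, registry = self._matrix(0.005)
        kept = filter_sparse_terms(matrix, registry, threshold=0.01)
        assert [d.name for d in kept] == [registry[0].name]

    def test_dense_steric_kept(self):
        matrix, registry = self._matrix(0.015)
        kept = filter_sparse_terms(matrix, registry, threshold=0.01)
        assert len(kept) == 2

    def test_named_terms_always_kept(self):
        matrix, registry = self._matrix(0.5)
        # the named gauss column is all zero yet must be retained
        kept = filter_sparse_terms(matrix, registry, threshold=0.01)
        assert registry[0].name in [d.name for d in kept]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_sparse_terms(pd.DataFrame(), [], threshold=0.01)


class TestScaling:
    def test_hand_computed_factors(self):
        matrix = pd.DataFrame({"t": [2.0, -4.0, 1.0]})
        s = fit_scaling(matrix)
        assert s.factors["t"] == pytest.approx(4.0)
        scaled = apply_scaling(matrix, s)
        np.testing.assert_allclose(scaled["t"], [0.5, -1.0, 0.25])

    def test_all_zero_column_factor_one(self):
        matrix = pd.DataFrame({"t": [0.0, 0.0]})
        s = fit_scaling(matrix)
        assert s.factors["t"] == 1.0
        assert apply_scaling(matrix, s)["t"].abs().max() == 0.0

    def test_scaling_properties_on_random_matrix(self, rng):
        matrix = pd.DataFrame(rng.normal(0, 5, (40, 6)),
                              columns=[f"t{i}" for i in range(6)])
        s = fit_scaling(matrix)
        scaled = apply_scaling(matrix, s)
        assert (scaled.abs().to_numpy() <= 1 + 1e-12).all()
        # each nonzero column attains |value| = 1
        np.testing.assert_allclose(scaled.abs().max(axis=0), 1.0)
        # sign preservation
        assert (np.sign(scaled.to_numpy()) == np.sign(matrix.to_numpy())).all()

    def test_termvector_rescaling_idempotent(self, rng):
        c = random_complex(rng)
        registry = default_registry()[:15]
        matrix = featurize_dataset([c], registry)
        s = fit_scaling(matrix)
        tv = featurize(c, registry)
        once = apply_scaling(tv, s)
        twice = apply_scaling(once, s)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.scaled

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            ScalingFactors(factors=pd.Series({"t": 0.0}), n_examples=3)
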