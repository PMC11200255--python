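"""Precalculated physicochemical terms and dataset-wide scaling.

Implements the smina/Vina-style term families evaluated on receptor-ligand
heavy-atom pairs within a distance cutoff, plus whole-ligand count terms.
All pairwise forms act on the *surface distance* ``ds = d - d0``, where ``d``
is the interatomic distance and ``d0`` the summed vdW radii of the pair:

* ``gauss(o,w,c)``:           sum of ``exp(-((ds-o)/w)^2)``
* ``repulsion(o,c)``:         sum of ``(ds-o)^2`` where ``ds < o``
* ``hydrophobic(g,b,c)``:     linear ramp, 1 below ``g``, 0 above ``b``,
                              over hydrophobic-hydrophobic pairs
* ``non_dir_h_bond(g,b,c)``:  the same ramp over donor/acceptor-complementary
                              pairs
* ``electrostatic(i,cap,c)``: sum of ``q1*q2/d^i``, each pair's value capped
                              at magnitude ``cap``
* ``atom_type_gaussian(t1,t2,o,w,c)``: Gaussian of ``ds`` summed over pairs
                              whose XS types match ``{t1, t2}``
* count family:               ``num_tors_div``, ``num_hydrophobic_atoms``,
                              ``num_heavy_atoms``, ``ligand_length``

Raw term vectors ``t_0`` are scaled to ``t = t_0 / max_e |t_0|`` with the
maximum taken over every example of the corpus, which places every term in
[-1, 1] without changing its sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import Atom, ComplexStructure, xs_type_table

__all__ = [
    "TermDescriptor",
    "TermVector",
    "ScalingFactors",
    "PairInteraction",
    "enumerate_pairs",
    "eval_term",
    "featurize",
    "featurize_dataset",
    "filter_sparse_terms",
    "fit_scaling",
    "apply_scaling",
    "default_registry",
    "named_physicochemical_terms",
    "save_registry",
    "load_registry",
]

FAMILIES = {"gauss", "repulsion", "hydrophobic", "non_dir_h_bond",
            "electrostatic", "atom_type_gaussian", "count"}


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


@dataclass(frozen=True)
class TermDescriptor:
    """One entry of the term registry, smina-style."""

    family: str
    params: dict = field(default_factory=dict)
    type_pair: tuple[str, str] | None = None
    count_kind: str | None = None  # for family == "count"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown term family {self.family!r}")
        c = self.params.get("c")
        if self.family != "count" and not (c is not None and c > 0):
            raise ValueError(f"{self.family}: cutoff c must be positive")
        if self.family in {"hydrophobic", "non_dir_h_bond"}:
            if not self.params["g"] < self.params["b"]:
                raise ValueError(f"{self.family}: require g < b")
        if self.family == "electrostatic" and not self.params.get("cap", 100) > 0:
            raise ValueError("electrostatic: cap must be positive")
        if self.family == "atom_type_gaussian" and self.type_pair is None:
            raise ValueError("atom_type_gaussian requires a type pair")

    def __hash__(self):
        return hash(self.name)

    @property
    def name(self) -> str:
        p = self.params
        if self.family == "count":
            return self.count_kind
        if self.family in {"gauss"}:
            return f"gauss(o={_fmt(p['o'])},_w={_fmt(p['w'])},_c={_fmt(p['c'])})"
        if self.family == "repulsion":
            return f"repulsion(o={_fmt(p['o'])},_c={_fmt(p['c'])})"
        if self.family in {"hydrophobic", "non_dir_h_bond"}:
            return (f"{self.family}(g={_fmt(p['g'])},_b={_fmt(p['b'])},"
                    f"_c={_fmt(p['c'])})")
        if self.family == "electrostatic":
            return (f"electrostatic(i={_fmt(p['i'])},_^={_fmt(p['cap'])},"
                    f"_c={_fmt(p['c'])})")
        t1, t2 = self.type_pair
        return (f"atom_type_gaussian(t1={t1},t2={t2},o={_fmt(p.get('o', 0))},"
                f"_w={_fmt(p.get('w', 1))},_c={_fmt(p['c'])})")

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params),
                "type_pair": list(self.type_pair) if self.type_pair else None,
                "count_kind": self.count_kind}

    @classmethod
    def from_dict(cls, d: dict) -> "TermDescriptor":
        pair = tuple(d["type_pair"]) if d.get("type_pair") else None
        return cls(family=d["family"], params=dict(d["params"]),
                   type_pair=pair, count_kind=d.get("count_kind"))


@dataclass
class TermVector:
    """Ordered term values for one complex, aligned to a registry."""

    entry_id: str
    names: list[str]
    values: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("term vector length does not match registry")


@dataclass
class ScalingFactors:
    """Per-term positive factors: the corpus-wide maxima of |t_0|."""

    factors: pd.Series  # index: term names; all > 0
    n_examples: int

    def __post_init__(self):
        if not (self.factors > 0).all():
            raise ValueError("all scaling factors must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"n_examples": self.n_examples,
             "factors": self.factors.to_dict()}, indent=1))

    @classmethod
    def from_json(cls, path) -> "ScalingFactors":
        d = json.loads(Path(path).read_text())
        return cls(factors=pd.Series(d["factors"]), n_examples=d["n_examples"])


@dataclass
class PairInteraction:
    """A receptor-ligand heavy-atom pair within a cutoff."""

    receptor_atom: int
    ligand_atom: int
    d: float
    d0: float
    g: float | None = None


# ---------------------------------------------------------------------------
# Pair geometry


class _PairContext:
    """Vectorized pair geometry and typing flags for one complex.

    Built once per complex and shared across all term evaluations; the pair
    list is produced by a KD-tree query whose contract is exact agreement
    with the brute-force all-pairs loop.
    """

    def __init__(self, complex_: ComplexStructure, cutoff: float):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.cutoff = cutoff
        rec = complex_.receptor_heavy()
        lig = complex_.ligand_heavy()
        self.rec_atoms, self.lig_atoms = rec, lig
        if rec and lig:
            rc = np.array([a.coords for a in rec])
            lc = np.array([a.coords for a in lig])
            pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), r=cutoff)
            ri, li = [], []
            for i, js in enumerate(pairs):
                ri.extend([i] * len(js))
                li.extend(js)
            self.ri = np.array(ri, dtype=int)
            self.li = np.array(li, dtype=int)
            if len(self.ri):
                diff = rc[self.ri] - lc[self.li]
                self.d = np.sqrt((diff * diff).sum(axis=1))
                order = np.lexsort((self.li, self.ri))
                self.ri, self.li, self.d = self.ri[order], self.li[order], self.d[order]
            else:
                self.d = np.zeros(0)
        else:
            self.ri = np.zeros(0, dtype=int)
            self.li = np.zeros(0, dtype=int)
            self.d = np.zeros(0)
        self.d0 = np.array([rec[i].vdw_radius + lig[j].vdw_radius
                            for i, j in zip(self.ri, self.li)]) if len(self.ri) else np.zeros(0)
        self.ds = self.d - self.d0
        self.q_prod = np.array([rec[i].partial_charge * lig[j].partial_charge
                                for i, j in zip(self.ri, self.li)]) if len(self.ri) else np.zeros(0)
        self.both_hydrophobic = np.array(
            [rec[i].is_hydrophobic and lig[j].is_hydrophobic
             for i, j in zip(self.ri, self.li)], dtype=bool) if len(self.ri) else np.zeros(0, bool)
        self.hbond = np.array(
            [(rec[i].is_donor and lig[j].is_acceptor)
             or (rec[i].is_acceptor and lig[j].is_donor)
             for i, j in zip(self.ri, self.li)], dtype=bool) if len(self.ri) else np.zeros(0, bool)
        self.pair_key = [frozenset((rec[i].xs_type, lig[j].xs_type))
                         for i, j in zip(self.ri, self.li)]


def enumerate_pairs(complex_: ComplexStructure, cutoff: float) -> list[PairInteraction]:
    """All receptor-ligand heavy-atom pairs with ``d <= cutoff`` (geometry only)."""
    ctx = _PairContext(complex_, cutoff)
    keep = ctx.d <= cutoff
    return [PairInteraction(receptor_atom=ctx.rec_atoms[i].index,
                            ligand_atom=ctx.lig_atoms[j].index,
                            d=float(d), d0=float(d0))
            for i, j, d, d0 in zip(ctx.ri[keep], ctx.li[keep],
                                   ctx.d[keep], ctx.d0[keep])]


# ---------------------------------------------------------------------------
# Term evaluation


def _ramp(ds: np.ndarray, good: float, bad: float) -> np.ndarray:
    # 1 for ds <= good, 0 for ds >= bad, linear in between
    return np.clip((bad - ds) / (bad - good), 0.0, 1.0)


def _eval_on_context(desc: TermDescriptor, ctx: _PairContext,
                     complex_: ComplexStructure) -> float:
    p = desc.params
    if desc.family == "count":
        lig = complex_.ligand_heavy()
        if desc.count_kind == "num_tors_div":
            return complex_.ligand_rotatable_bonds / p.get("divisor", 5.0)
        if desc.count_kind == "num_hydrophobic_atoms":
            return float(sum(a.is_hydrophobic for a in lig))
        if desc.count_kind == "num_heavy_atoms":
            return float(len(lig))
        if desc.count_kind == "ligand_length":
            if len(lig) < 2:
                return 0.0
            coords = np.array([a.coords for a in lig])
            diff = coords[:, None, :] - coords[None, :, :]
            return float(np.sqrt((diff ** 2).sum(-1)).max())
        raise ValueError(f"unknown count term {desc.count_kind!r}")

    within = ctx.d <= p["c"]
    ds = ctx.ds[within]
    if desc.family == "gauss":
        return float(np.exp(-(((ds - p["o"]) / p["w"]) ** 2)).sum())
    if desc.family == "repulsion":
        r = ds - p["o"]
        return float((r[ds < p["o"]] ** 2).sum())
    if desc.family == "hydrophobic":
        mask = ctx.both_hydrophobic[within]
        return float(_ramp(ds[mask], p["g"], p["b"]).sum())
    if desc.family == "non_dir_h_bond":
        mask = ctx.hbond[within]
        return float(_ramp(ds[mask], p["g"], p["b"]).sum())
    if desc.family == "electrostatic":
        d = ctx.d[within]
        vals = ctx.q_prod[within] / np.power(d, p["i"])
        return float(np.clip(vals, -p["cap"], p["cap"]).sum())
    if desc.family == "atom_type_gaussian":
        key = frozenset(desc.type_pair)
        mask = np.array([k == key for k in
                         (ctx.pair_key[i] for i in np.flatnonzero(within))], dtype=bool)
        if not mask.any():
            return 0.0
        o, w = p.get("o", 0.0), p.get("w", 1.0)
        return float(np.exp(-(((ds[mask] - o) / w) ** 2)).sum())
    raise ValueError(f"unknown term family {desc.family!r}")


def eval_term(desc: TermDescriptor, complex_: ComplexStructure) -> float:
    """Evaluate a single term on one complex (builds its own pair context)."""
    cutoff = desc.params.get("c", 8.0)
    return _eval_on_context(desc, _PairContext(complex_, cutoff), complex_)


def featurize(complex_: ComplexStructure,
              registry: list[TermDescriptor]) -> TermVector:
    """Compute the raw (unscaled) term vector ``t_0`` for one complex."""
    if not registry:
        raise ValueError("registry must be nonempty")
    cutoffs = {d.params.get("c", 8.0) for d in registry if d.family != "count"}
    max_cut = max(cutoffs) if cutoffs else 8.0
    ctx = _PairContext(complex_, max_cut)

    values = np.empty(len(registry))
    # fast path: all atom_type_gaussian terms sharing (o, w) evaluated in one pass
    atg = [(k, d) for k, d in enumerate(registry) if d.family == "atom_type_gaussian"]
    atg_done = set()
    if atg:
        by_shape: dict[tuple, list[tuple[int, TermDescriptor]]] = {}
        for k, d in atg:
            shape = (d.params.get("o", 0.0), d.params.get("w", 1.0), d.params["c"])
            by_shape.setdefault(shape, []).append((k, d))
        for (o, w, c), group in by_shape.items():
            within = ctx.d <= c
            gvals = np.exp(-(((ctx.ds[within] - o) / w) ** 2))
            keys = [ctx.pair_key[i] for i in np.flatnonzero(within)]
            sums: dict[frozenset, float] = {}
            for key, gv in zip(keys, gvals):
                sums[key] = sums.get(key, 0.0) + gv
            for k, d in group:
                values[k] = sums.get(frozenset(d.type_pair), 0.0)
                atg_done.add(k)
    for k, desc in enumerate(registry):
        if k in atg_done:
            continue
        try:
            values[k] = _eval_on_context(desc, ctx, complex_)
        except Exception as exc:
            raise type(exc)(f"term {desc.name!r}: {exc}") from exc
    return TermVector(entry_id=complex_.entry_id,
                      names=[d.name for d in registry], values=values)


def featurize_dataset(complexes, registry) -> pd.DataFrame:
    """Raw term matrix (entries x terms) for a collection of complexes."""
    rows = [featurize(c, registry) for c in complexes]
    return pd.DataFrame([tv.values for tv in rows],
                        index=[tv.entry_id for tv in rows],
                        columns=[d.name for d in registry])


# ---------------------------------------------------------------------------
# Sparsity filter and scaling


def filter_sparse_terms(matrix: pd.DataFrame, registry: list[TermDescriptor],
                        threshold: float = 0.01) -> list[TermDescriptor]:
    """Drop atom_type_gaussian terms nonzero in fewer than ``threshold`` of examples.

    Non-steric terms are retained unconditionally. The nonzero fraction is
    computed over the full matrix (training and testing examples jointly).
    """
    if matrix.empty:
        raise ValueError("term matrix is empty")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    kept = []
    for desc in registry:
        if desc.family != "atom_type_gaussian":
            kept.append(desc)
            continue
        frac = float((matrix[desc.name] != 0).mean())
        if frac >= threshold:
            kept.append(desc)
    return kept


def fit_scaling(matrix: pd.DataFrame) -> ScalingFactors:
    """Per-term max-|t_0| over all examples; all-zero terms get factor 1."""
    if matrix.empty:
        raise ValueError("term matrix is empty")
    factors = matrix.abs().max(axis=0)
    factors[factors == 0] = 1.0
    return ScalingFactors(factors=factors.astype(float), n_examples=len(matrix))


def apply_scaling(v, s: ScalingFactors):
    """Scale a TermVector or a term matrix by stored factors (idempotent-safe).

    A :class:`TermVector` already marked ``scaled`` is returned unchanged, so
    accidental double application cannot shrink values.
    """
    if isinstance(v, pd.DataFrame):
        missing = [c for c in v.columns if c not in s.factors.index]
        if missing:
            raise ValueError(f"no scaling factor for terms: {missing[:3]}")
        return v / s.factors[v.columns]
    if isinstance(v, TermVector):
        if v.scaled:
            return v
        try:
            f = s.factors[v.names].to_numpy()
        except KeyError as exc:
            raise ValueError(f"scaling factors do not cover registry: {exc}") from exc
        return TermVector(entry_id=v.entry_id, names=list(v.names),
                          values=v.values / f, scaled=True)
    raise TypeError("expected TermVector or DataFrame")


# ---------------------------------------------------------------------------
# Registries


def named_physicochemical_terms(cutoff: float = 8.0) -> list[TermDescriptor]:
    """The named non-steric terms: Vina/smina terms, electrostatics, counts."""
    return [
        TermDescriptor("gauss", {"o": 0.0, "w": 0.5, "c": cutoff}),
        TermDescriptor("gauss", {"o": 3.0, "w": 2.0, "c": cutoff}),
        TermDescriptor("repulsion", {"o": 0.0, "c": cutoff}),
        TermDescriptor("hydrophobic", {"g": 0.5, "b": 1.5, "c": cutoff}),
        TermDescriptor("non_dir_h_bond", {"g": -0.7, "b": 0.0, "c": cutoff}),
        TermDescriptor("electrostatic", {"i": 1, "cap": 100.0, "c": cutoff}),
        TermDescriptor("electrostatic", {"i": 2, "cap": 100.0, "c": cutoff}),
        TermDescriptor("count", count_kind="num_tors_div",
                       params={"divisor": 5.0}),
        TermDescriptor("count", count_kind="num_hydrophobic_atoms"),
        TermDescriptor("count", count_kind="num_heavy_atoms"),
        TermDescriptor("count", count_kind="ligand_length"),
    ]


def default_registry(cutoff: float = 8.0, atg_width: float = 1.0) -> list[TermDescriptor]:
    """Named terms plus all 325 unordered-pair atom_type_gaussian terms.

    The steric set enumerates every unordered pair over the 25 canonical
    heavy XS types (25*26/2 = 325 candidates); downstream, the corpus-level
    sparsity filter reduces these to the retained registry.
    """
    registry = named_physicochemical_terms(cutoff)
    pair_types = xs_type_table()["pair_types"]
    for a_idx, t1 in enumerate(pair_types):
        for t2 in pair_types[a_idx:]:
            registry.append(TermDescriptor(
                "atom_type_gaussian",
                {"o": 0.0, "w": atg_width, "c": cutoff},
                type_pair=(t1, t2)))
    return registry


def save_registry(registry: list[TermDescriptor], path) -> None:
    Path(path).write_text(json.dumps([d.to_dict() for d in registry], indent=1))


def load_registry(path) -> list[TermDescriptor]:
    return [TermDescriptor.from_dict(d) for d in json.loads(Path(path).read_text())]
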