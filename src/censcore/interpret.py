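"""Interpretability toolkit: per-atom attribution, weight z-scores,
weight-space embedding and virtual-screening metrics.

The pairwise steric (atom_type_gaussian) terms are directly attributable to
individual receptor/ligand atom pairs: for every pair within the cutoff, the
Gaussian value ``g`` is divided by the term's dataset scaling factor,
multiplied by the complex-specific predicted weight, and split half to the
receptor atom and half to the ligand atom; atoms in several pairs accumulate
sums. The per-atom values therefore conserve the summed weighted scaled
steric contribution exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cenmodel import WeightVector
from .structio import ComplexStructure
from .terms import ScalingFactors, TermDescriptor, _PairContext

__all__ = ["AttributionMap", "ZScoreReport", "ScreenResult", "EmbeddingResult",
           "attribute_atoms", "weight_zscores", "embed_weights", "screen_metrics"]


@dataclass
class AttributionMap:
    """Per-atom summed half-contributions and per-term totals (score units)."""

    per_atom: dict[int, float]
    per_term_totals: dict[str, float]
    entry_id: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.per_term_totals.values()))


def attribute_atoms(complex_: ComplexStructure, weights: WeightVector,
                    scaling: ScalingFactors,
                    registry: list[TermDescriptor]) -> AttributionMap:
    """Per-atom contributions of the atom_type_gaussian terms.

    For each steric descriptor with weight ``w`` and scaling factor ``f``,
    every matching pair within the cutoff contributes ``v = g / f * w``,
    half to each atom of the pair.
    """
    if len(weights.weights) != len(registry):
        raise ValueError("weight vector not aligned to registry")
    atg = [(k, d) for k, d in enumerate(registry)
           if d.family == "atom_type_gaussian"]
    missing = [d.name for _, d in atg if d.name not in scaling.factors.index]
    if missing:
        raise ValueError(f"missing scaling factors for {missing[:3]}")

    per_atom: dict[int, float] = {}
    per_term: dict[str, float] = {}
    cutoffs = {d.params["c"] for _, d in atg} or {8.0}
    ctx = _PairContext(complex_, max(cutoffs))
    for k, desc in atg:
        p = desc.params
        key = frozenset(desc.type_pair)
        factor = float(scaling.factors[desc.name])
        w = float(weights.weights[k])
        total = 0.0
        for n in range(len(ctx.d)):
            if ctx.d[n] > p["c"] or ctx.pair_key[n] != key:
                continue
            g = float(np.exp(-(((ctx.ds[n] - p.get("o", 0.0)) / p.get("w", 1.0)) ** 2)))
            v = g / factor * w
            ra = ctx.rec_atoms[ctx.ri[n]].index
            la = ctx.lig_atoms[ctx.li[n]].index
            per_atom[ra] = per_atom.get(ra, 0.0) + v / 2.0
            per_atom[la] = per_atom.get(la, 0.0) + v / 2.0
            total += v
        per_term[desc.name] = total
    return AttributionMap(per_atom=per_atom, per_term_totals=per_term,
                          entry_id=complex_.entry_id)


@dataclass
class ZScoreReport:
    """Per-term comparison of target-set mean weights to a reference corpus."""

    terms: list[str]
    target_mean: np.ndarray
    reference_mean: np.ndarray
    reference_std: np.ndarray
    abs_z: np.ndarray            # nan where reference_std == 0
    flagged: list[str] = field(default_factory=list)
    std_convention: str = "population"

    def sorted_by_z(self) -> list[tuple[str, float]]:
        order = np.argsort(-np.nan_to_num(self.abs_z, nan=-np.inf))
        return [(self.terms[i], float(self.abs_z[i])) for i in order]


def weight_zscores(target_weights, reference_weights,
                   terms: list[str] | None = None) -> ZScoreReport:
    """|z| of target-mean weights against the reference mean and population std.

    ``target_weights`` and ``reference_weights`` are sequences of
    :class:`WeightVector` (or plain arrays) over one aligned registry.
    """
    def _stack(ws):
        return np.stack([w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
                         for w in ws])

    target = _stack(target_weights)
    ref = _stack(reference_weights)
    if ref.shape[0] < 2:
        raise ValueError("need at least two reference weight vectors")
    if target.shape[1] != ref.shape[1]:
        raise ValueError("target and reference registries are not aligned")
    n = target.shape[1]
    names = list(terms) if terms is not None else [f"term_{i}" for i in range(n)]
    t_mean = target.mean(axis=0)
    r_mean = ref.mean(axis=0)
    r_std = ref.std(axis=0)  # population std
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_z = np.abs(t_mean - r_mean) / r_std
    abs_z[r_std == 0] = np.nan
    flagged = [names[i] for i in np.flatnonzero(r_std == 0)]
    return ZScoreReport(terms=names, target_mean=t_mean, reference_mean=r_mean,
                        reference_std=r_std, abs_z=abs_z, flagged=flagged)


@dataclass
class EmbeddingResult:
    coords: np.ndarray                 # (n, 2)
    kmeans_consistency: float          # ARI of k-means labels: original vs 2D
    silhouette_2d: float


def embed_weights(weight_set, seed: int = 0, n_clusters: int = 2,
                  perplexity: float | None = None) -> EmbeddingResult:
    """t-SNE projection of weight vectors to 2D, with a k-means sanity check.

    The consistency score is the adjusted Rand index between k-means labels
    computed in the original weight space and on the embedded points: values
    near 1 mean similar weight vectors map to adjacent 2D regions.
    """
    from sklearn.cluster import KMeans
    from sklearn.manifold import TSNE
    from sklearn.metrics import adjusted_rand_score, silhouette_score

    W = np.stack([w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
                  for w in weight_set])
    n = W.shape[0]
    if n < 5:
        raise ValueError("need at least 5 weight vectors to embed")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    coords = TSNE(n_components=2, random_state=seed, init="pca",
                  perplexity=perplexity).fit_transform(W)
    k = min(n_clusters, n - 1)
    km_orig = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(W)
    km_2d = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(coords)
    ari = float(adjusted_rand_score(km_orig, km_2d))
    sil = (float(silhouette_score(coords, km_orig))
           if len(set(km_orig)) > 1 else 0.0)
    return EmbeddingResult(coords=np.asarray(coords, float),
                           kmeans_consistency=ari, silhouette_2d=sil)


@dataclass
class ScreenResult:
    auroc: float
    enrichment: dict[float, float]     # top-fraction -> EF
    n_actives: int
    n_total: int


def screen_metrics(scores, labels,
                   top_fractions=(0.01, 0.05, 0.10)) -> ScreenResult:
    """AUROC (rank statistic, tie-averaged) and enrichment factors.

    ``labels`` are 1 for actives, 0 for inactives; higher scores rank better.
    EF at fraction f is the active rate in the top ``ceil(f*N)`` compounds
    divided by the overall active rate.
    """
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("screen needs both actives and inactives")
    auroc = float(roc_auc_score(labels, scores))
    n = len(scores)
    n_act = int(labels.sum())
    order = np.argsort(-scores, kind="stable")
    enrichment = {}
    for f in top_fractions:
        top = max(1, int(np.ceil(f * n)))
        hits = int(labels[order[:top]].sum())
        enrichment[f] = (hits / top) / (n_act / n)
    return ScreenResult(auroc=auroc, enrichment=enrichment,
                        n_actives=n_act, n_total=n)
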