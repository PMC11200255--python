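"""Attribution conservation, z-scores, embedding and screening metrics."""

import numpy as np
import pandas as pd
import pytest

from censcore.cenmodel import WeightVector, predict_affinity
from censcore.interpret import (attribute_atoms, embed_weights, screen_metrics,
                                weight_zscores)
from censcore.terms import (ScalingFactors, TermDescriptor, TermVector,
                            apply_scaling, featurize, fit_scaling,
                            featurize_dataset)

from conftest import make_complex, random_complex


def _atg(pair, c=8.0):
    return TermDescriptor("atom_type_gaussian", {"o": 0.0, "w": 1.0, "c": c},
                          type_pair=pair)


CC = ("AliphaticCarbonXSHydrophobe", "AliphaticCarbonXSHydrophobe")


class TestAttribution:
    def test_half_half_single_pair(self):
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 3.8), {"n_h": 4, "bonded": ()})])
        registry = [_atg(CC)]
        scaling = ScalingFactors(pd.Series({registry[0].name: 10.0}), 1)
        weights = WeightVector("toy", np.array([2.0]))
        amap = attribute_atoms(c, weights, scaling, registry)
        # v = g/f*w = 1/10*2 = 0.2, split 0.1 / 0.1
        assert amap.per_atom[0] == pytest.approx(0.1)
        assert amap.per_atom[1] == pytest.approx(0.1)

    def test_atom_in_multiple_pairs_accumulates(self):
        # one ligand C against two receptor C at different distances
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()}),
                          ("C", (0, 0, 7.6), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 3.8), {"n_h": 4, "bonded": ()})])
        registry = [_atg(CC)]
        scaling = ScalingFactors(pd.Series({registry[0].name: 1.0}), 1)
        weights = WeightVector("toy", np.array([1.0]))
        amap = attribute_atoms(c, weights, scaling, registry)
        lig_idx = c.ligand_atoms[0].index
        v1 = v2 = 1.0  # both pairs at ds = 0
        assert amap.per_atom[lig_idx] == pytest.approx((v1 + v2) / 2)
        assert amap.total == pytest.approx(v1 + v2)

    def test_conservation_against_predictor(self, rng):
        """Sum of per-atom values equals the weighted scaled steric
        contribution reported by the affinity decomposition."""
        registry = [TermDescriptor("gauss", {"o": 0.0, "w": 0.5, "c": 8.0}),
                    _atg(CC), _atg(("OxygenXSAcceptor", "NitrogenXSDonor")),
                    _atg(("AliphaticCarbonXSHydrophobe", "OxygenXSDonorAcceptor"))]
        complexes = [random_complex(rng, 20, 8) for _ in range(4)]
        scaling = fit_scaling(featurize_dataset(complexes, registry))
        for c in complexes:
            weights = WeightVector(c.entry_id, rng.normal(size=len(registry)))
            scaled = apply_scaling(featurize(c, registry), scaling)
            pred = predict_affinity(weights, scaled)
            amap = attribute_atoms(c, weights, scaling, registry)
            steric_contrib = sum(
                pred.per_term_contributions[k]
                for k, d in enumerate(registry)
                if d.family == "atom_type_gaussian")
            assert sum(amap.per_atom.values()) == pytest.approx(
                steric_contrib, rel=1e-9, abs=1e-12)
            assert amap.total == pytest.approx(steric_contrib, rel=1e-9,
                                               abs=1e-12)

    def test_missing_scaling_rejected(self):
        c = make_complex([("C", (0, 0, 0), {"n_h": 4, "bonded": ()})],
                         [("C", (0, 0, 3.8), {"n_h": 4, "bonded": ()})])
        scaling = ScalingFactors(pd.Series({"other": 1.0}), 1)
        with pytest.raises(ValueError):
            attribute_atoms(c, WeightVector("t", np.ones(1)), scaling, [_atg(CC)])


class TestZScores:
    def test_printed_worked_example(self):
        """Target mean -7.52 vs reference -5.15 +- 1.72 gives |z| = 1.38."""
        target = [np.array([-7.52])]
        # two reference vectors realizing mean -5.15, population std 1.72
        ref = [np.array([-5.15 - 1.72]), np.array([-5.15 + 1.72])]
        report = weight_zscores(target, ref, terms=["electrostatic(i=1)"])
        assert report.abs_z[0] == pytest.approx(1.38, abs=0.005)

    def test_equal_means_zero(self, rng):
        ref = rng.normal(size=(10, 3))
        target = [ref.mean(axis=0)]
        report = weight_zscores(target, list(ref))
        np.testing.assert_allclose(report.abs_z, 0.0, atol=1e-12)

    def test_zero_std_flagged(self):
        ref = [np.array([1.0, 2.0]), np.array([1.0, 3.0])]
        report = weight_zscores([np.array([5.0, 2.5])], ref, terms=["a", "b"])
        assert report.flagged == ["a"]
        assert np.isnan(report.abs_z[0]) and np.isfinite(report.abs_z[1])

    def test_affine_invariance(self, rng):
        """|z| is invariant to a common affine map applied to one term's
        weights in both the target and reference sets."""
        ref = rng.normal(size=(8, 2))
        target = rng.normal(size=(3, 2))
        base = weight_zscores(list(target), list(ref))
        a, b = 3.7, -1.2
        report = weight_zscores(list(target * a + b), list(ref * a + b))
        np.testing.assert_allclose(report.abs_z, base.abs_z, rtol=1e-9)

    def test_single_reference_rejected(self):
        with pytest.raises(ValueError):
            weight_zscores([np.ones(2)], [np.ones(2)])


class TestEmbedding:
    def _two_cluster_weights(self, rng, n=30):
        a = rng.normal(0, 0.3, size=(n // 2, 6)) + np.array([5, 0, 0, 0, 0, 0])
        b = rng.normal(0, 0.3, size=(n // 2, 6)) - np.array([5, 0, 0, 0, 0, 0])
        return np.vstack([a, b])

    def test_separated_clusters_stay_separated(self, rng):
        W = self._two_cluster_weights(rng)
        result = embed_weights(W, seed=0, n_clusters=2)
        assert result.coords.shape == (30, 2)
        assert result.silhouette_2d > 0
        assert result.kmeans_consistency > 0.9

    def test_duplicates_land_together(self, rng):
        W = self._two_cluster_weights(rng)
        W[1] = W[0]
        coords = embed_weights(W, seed=0).coords
        d01 = np.linalg.norm(coords[0] - coords[1])
        spread = np.linalg.norm(coords.max(0) - coords.min(0))
        assert d01 < 0.05 * spread

    def test_seeded_determinism(self, rng):
        W = self._two_cluster_weights(rng)
        c1 = embed_weights(W, seed=3).coords
        c2 = embed_weights(W, seed=3).coords
        np.testing.assert_array_equal(c1, c2)

    def test_too_few_vectors_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_weights(rng.normal(size=(4, 3)), seed=0)


def brute_force_auroc(scores, labels):
    """Fraction of correctly ordered active-inactive pairs (ties half)."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    act = scores[labels == 1]
    inact = scores[labels == 0]
    wins = ties = 0
    for a in act:
        for i in inact:
            wins += a > i
            ties += a == i
    return (wins + 0.5 * ties) / (len(act) * len(inact))


class TestScreenMetrics:
    def test_perfect_ranking(self):
        result = screen_metrics([5, 4, 3, 2, 1], [1, 1, 0, 0, 0])
        assert result.auroc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        result = screen_metrics([1.0] * 10, [1] * 4 + [0] * 6)
        assert result.auroc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        scores = [9.1, 8.7, 8.7, 7.5, 7.2, 6.9, 6.9, 5.5, 4.2, 3.0]
        labels = [1, 0, 1, 1, 0, 0, 1, 0, 0, 0]
        result = screen_metrics(scores, labels)
        assert result.auroc == pytest.approx(brute_force_auroc(scores, labels))

    def test_oracle_equivalence_random(self, rng):
        for _ in range(10):
            scores = rng.normal(size=40).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            result = screen_metrics(scores, labels)
            assert result.auroc == pytest.approx(
                brute_force_auroc(scores, labels))

    def test_enrichment_factor(self):
        # top 10% of 20 compounds = 2 slots, both active; 4/20 active overall
        scores = np.linspace(20, 1, 20)
        labels = [1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        result = screen_metrics(scores, labels, top_fractions=(0.1,))
        assert result.enrichment[0.1] == pytest.approx((2 / 2) / (4 / 20))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            screen_metrics([1, 2, 3], [1, 1, 1])
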