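import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pahscape.cluster import (
    SubpopulationNamingError,
    assign_knn,
    build_feature_matrix,
    consensus_cluster,
    name_subpopulations,
)
from pahscape.model import PeakFeatures


def _feat(gid, act, phe, bh4, width):
    low = phe / 2
    return PeakFeatures(gid, act, phe, bh4, low, low + width, width, True, act)


def _planted_features(rng, centers, n_each, spread=0.05):
    feats = []
    for ci, (act, phe, bh4, width) in enumerate(centers):
        for i in range(n_each):
            feats.append(
                _feat(
                    f"C{ci}_{i:02d}",
                    act * math.exp(spread * rng.standard_normal()),
                    phe * math.exp(spread * rng.standard_normal()),
                    bh4 * math.exp(spread * rng.standard_normal()),
                    width * math.exp(spread * rng.standard_normal()),
                )
            )
    return feats


class TestFeatureMatrix:
    def test_identical_features_standardize_identically(self):
        feats = [_feat(f"G{i}", 10.0, 300.0, 100.0, 500.0) for i in range(3)]
        feats.append(_feat("G9", 20.0, 400.0, 80.0, 700.0))
        fm = build_feature_matrix(feats)
        np.testing.assert_allclose(fm.values[0], fm.values[1])
        np.testing.assert_allclose(fm.values[1], fm.values[2])

    def test_columns_are_z_standardized(self):
        rng = np.random.default_rng(0)
        feats = _planted_features(rng, [(10, 300, 100, 500), (25, 600, 120, 900)], 10)
        fm = build_feature_matrix(feats)
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fm.values.std(axis=0), 1.0, rtol=1e-12)

    def test_inverse_transform_round_trip(self):
        rng = np.random.default_rng(1)
        feats = _planted_features(rng, [(10, 300, 100, 500), (25, 600, 120, 900)], 8)
        fm = build_feature_matrix(feats)
        np.testing.assert_allclose(fm.inverse_transform(fm.values), fm.raw, atol=1e-12)

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError):
            build_feature_matrix([_feat("G1", 10, 300, 100, 500)])


class TestConsensusCluster:
    def test_three_planted_clusters_recovered(self):
        """Well-separated planted groups: k=3 selected, partition exact."""
        rng = np.random.default_rng(7)
        centers = [(5.0, 100.0, 60.0, 150.0), (12.0, 330.0, 100.0, 600.0), (28.0, 700.0, 130.0, 1500.0)]
        feats = _planted_features(rng, centers, 10)
        fm = build_feature_matrix(feats)
        cr = consensus_cluster(fm, k_range=range(2, 7), n_resamples=100, seed=3)
        assert cr.k_selected == 3
        truth = [i // 10 for i in range(30)]
        assert adjusted_rand_score(truth, cr.labels) == pytest.approx(1.0)

    def test_perfect_separation_makes_binary_consensus(self):
        feats = [_feat(f"A{i}", 5.0, 100.0, 60.0, 150.0) for i in range(4)] + [
            _feat(f"B{i}", 30.0, 700.0, 130.0, 1500.0) for i in range(4)
        ]
        fm = build_feature_matrix(feats)
        cr = consensus_cluster(fm, k_range=(2,), n_resamples=50, seed=0)
        cm = cr.consensus_matrix
        same = np.zeros((8, 8), dtype=bool)
        same[:4, :4] = same[4:, 4:] = True
        assert np.all(cm[same] == 1.0)
        assert np.all(cm[~same] == 0.0)

    def test_consensus_matrix_invariants(self, clustered):
        _, cr, _, _ = clustered
        cm = cr.consensus_matrix
        np.testing.assert_allclose(cm, cm.T)
        np.testing.assert_allclose(np.diag(cm), 1.0)
        assert cm.min() >= 0.0 and cm.max() <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        centers = [(5.0, 100.0, 60.0, 150.0), (12.0, 330.0, 100.0, 600.0), (28.0, 700.0, 130.0, 1500.0)]
        feats = _planted_features(rng, centers, 8)
        fm1 = build_feature_matrix(feats)
        perm = rng.permutation(len(feats))
        fm2 = build_feature_matrix([feats[i] for i in perm])
        cr1 = consensus_cluster(fm1, k_range=range(2, 5), n_resamples=60, seed=5)
        cr2 = consensus_cluster(fm2, k_range=range(2, 5), n_resamples=60, seed=5)
        assert cr1.k_selected == cr2.k_selected
        lab1 = dict(zip(cr1.genotype_ids, cr1.labels))
        lab2 = dict(zip(cr2.genotype_ids, cr2.labels))
        assert lab1 == lab2

    def test_degenerate_input_rejected(self):
        feats = [_feat(f"G{i}", 10.0, 300.0, 100.0, 500.0) for i in range(10)]
        fm = build_feature_matrix(feats)
        with pytest.raises(ValueError, match="no cluster structure"):
            consensus_cluster(fm, k_range=(2, 3), n_resamples=10, seed=0)


class TestNaming:
    def test_archetype_cohort_names_match_planted_labels(self, clustered, planted_labels):
        _, cr, mapping, assignments = clustered
        assert mapping is not None
        named = {g: a.label for g, a in assignments.items() if a.source == "consensus"}
        agree = sum(named[g] == planted_labels[g] for g in named)
        assert agree / len(named) >= 0.9

    def test_naming_requires_five_clusters(self, clustered):
        fm, cr, _, _ = clustered
        import dataclasses

        wrong_k = dataclasses.replace(cr, k_selected=4)
        wt = PeakFeatures("WT", 100.0, 330.0, 101.0, 80.0, 1361.0, 1281.0, True, 100.0)
        with pytest.raises(SubpopulationNamingError):
            name_subpopulations(wrong_k, fm, wt)


class TestKnn:
    def test_reference_row_with_k1_returns_own_label(self, clustered):
        fm, cr, mapping, assignments = clustered
        labels = np.array([assignments[g].label for g in fm.genotype_ids])
        for i in (0, 5, 17):
            gid = fm.genotype_ids[i]
            feats = _unstandardized_features(fm, i, gid)
            out = assign_knn(feats, fm, labels, k=1)
            assert out.label == labels[i]
            assert out.source == "knn"

    def test_matches_brute_force_distances(self, clustered):
        fm, _, _, assignments = clustered
        labels = np.array([assignments[g].label for g in fm.genotype_ids])
        query = _unstandardized_features(fm, 3, "query", jitter=0.1)
        out = assign_knn(query, fm, labels, k=5)
        d = np.linalg.norm(fm.values - fm.transform(query), axis=1)
        nearest = np.argsort(d, kind="stable")[:5]
        votes = {}
        for i in nearest:
            votes[int(labels[i])] = votes.get(int(labels[i]), 0) + 1
        assert out.neighbor_votes == votes

    def test_leave_one_out_accuracy_on_cohort(self, clustered):
        fm, _, _, assignments = clustered
        labels = np.array([assignments[g].label for g in fm.genotype_ids])
        hits = 0
        for i, gid in enumerate(fm.genotype_ids):
            keep = [j for j in range(fm.n) if j != i]
            sub = build_feature_matrix(
                [_unstandardized_features(fm, j, fm.genotype_ids[j]) for j in keep]
            )
            out = assign_knn(_unstandardized_features(fm, i, gid), sub, labels[keep], k=5)
            hits += out.label == labels[i]
        assert hits / fm.n >= 0.9

    def test_k_larger_than_reference_rejected(self, clustered):
        fm, _, _, assignments = clustered
        labels = np.array([assignments[g].label for g in fm.genotype_ids])
        with pytest.raises(ValueError):
            assign_knn(_unstandardized_features(fm, 0, "q"), fm, labels, k=fm.n + 1)


def _unstandardized_features(fm, i, gid, jitter=0.0):
    act, lphe, lbh4, lwidth = fm.raw[i]
    if jitter:
        act += jitter
    phe, width = math.exp(lphe), math.exp(lwidth)
    return _feat(gid, act, phe, math.exp(lbh4), width)
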