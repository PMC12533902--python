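"""Hybrid selection: ReliefF oracle equivalence, fusion limits, recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from cilad import synthetic_data as sd
from cilad.datatypes import FeatureTable
from cilad.select import (combine_scores, pearson_scores, relieff_weights,
                          score_features, select_top)


def brute_force_relieff(X, y, k, literal_sign=False):
    """Independent ReliefF: explicit loops, full distance matrix, stable
    neighbor sort.  Same definition, structurally independent path."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    Xs = (X - lo) / rng_
    n, d = Xs.shape
    classes = sorted(set(y.tolist()))
    priors = {c: np.sum(y == c) / n for c in classes}
    w = np.zeros(d)
    for i in range(n):
        dists = [sum(abs(Xs[i, f] - Xs[j, f]) for f in range(d)) for j in range(n)]
        nhd = np.zeros(d)
        nmad = np.zeros(d)
        same = sorted((j for j in range(n) if y[j] == y[i] and j != i),
                      key=lambda j: (dists[j], j))[:k]
        for f in range(d):
            nhd[f] = np.mean([abs(Xs[i, f] - Xs[j, f]) for j in same])
        for c in classes:
            if c == y[i]:
                continue
            other = sorted((j for j in range(n) if y[j] == c),
                           key=lambda j: (dists[j], j))[:k]
            coeff = priors[c] / (1.0 - priors[y[i]])
            for f in range(d):
                nmad[f] += coeff * np.mean([abs(Xs[i, f] - Xs[j, f]) for j in other])
        if literal_sign:
            w += (nhd - nmad) / n
        else:
            w += (nmad - nhd) / n
    return w


class TestReliefF:
    def test_separating_feature_outweighs_constant(self, tiny_features):
        w = relieff_weights(tiny_features, k_neighbors=3)
        assert w[0] > w[3]
        assert w[3] == pytest.approx(0.0, abs=1e-12)
        # the brute-force oracle agrees on the ordering
        wb = brute_force_relieff(tiny_features.values, tiny_features.labels, 3)
        assert np.argmax(w) == np.argmax(wb) == 0

    @pytest.mark.parametrize("seed,n,k", [(0, 30, 3), (1, 50, 5), (2, 40, 2)])
    def test_oracle_equivalence_small_n(self, seed, n, k):
        rng = np.random.default_rng(seed)
        n_classes = 2 + seed % 2
        y = rng.integers(0, n_classes, n)
        while len(set(y.tolist())) < n_classes or min(np.bincount(y)) <= k:
            y = rng.integers(0, n_classes, n)
        X = rng.normal(0, 1, (n, 5)) + y[:, None] * rng.normal(0, 1, 5)
        table = FeatureTable([f"f{i}" for i in range(5)], X, y)
        w = relieff_weights(table, k_neighbors=k)
        wb = brute_force_relieff(X, y, k)
        assert np.allclose(w, wb, atol=1e-12)

    def test_literal_sign_flag_negates(self, tiny_features):
        w = relieff_weights(tiny_features, k_neighbors=3)
        wl = relieff_weights(tiny_features, k_neighbors=3, literal_sign=True)
        assert np.allclose(w, -wl, atol=1e-12)

    def test_deterministic_under_subsampling_seed(self, tiny_features):
        a = relieff_weights(tiny_features, k_neighbors=3, n_iterations=20, seed=5)
        b = relieff_weights(tiny_features, k_neighbors=3, n_iterations=20, seed=5)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        t = FeatureTable(["a"], np.zeros((10, 1)), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            relieff_weights(t)

    def test_scale_invariance_of_combined_score(self, tiny_features):
        s1 = score_features(tiny_features, seed=0)
        scaled = tiny_features.values.copy()
        scaled[:, 0] *= 1000.0
        t2 = FeatureTable(tiny_features.names, scaled, tiny_features.labels)
        s2 = score_features(t2, seed=0)
        assert np.allclose(s1.combined, s2.combined, atol=1e-9)


class TestPearson:
    def test_perfect_correlations(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        t = FeatureTable(["pos", "neg"],
                         np.column_stack([y.astype(float), -y.astype(float)]), y)
        tau = pearson_scores(t)
        assert tau[0] == pytest.approx(1.0)
        assert tau[1] == pytest.approx(-1.0)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        t = FeatureTable(["rand"], rng.normal(0, 1, (10_000, 1)), y)
        assert abs(pearson_scores(t)[0]) < 0.05

    def test_constant_feature_warns_and_zero(self):
        t = FeatureTable(["const"], np.ones((10, 1)),
                         np.array([0, 1] * 5))
        with pytest.warns(UserWarning):
            assert pearson_scores(t)[0] == 0.0


class TestCombineAndSelect:
    def test_alpha_limits_reduce_to_single_signal(self, tiny_features):
        rf = relieff_weights(tiny_features, k_neighbors=3)
        pc = pearson_scores(tiny_features)
        only_rf = combine_scores(rf, pc, alpha=1.0)
        only_pc = combine_scores(rf, pc, alpha=0.0)
        assert np.array_equal(np.argsort(-only_rf.combined, kind="stable"),
                              np.argsort(-only_rf.relieff_scaled, kind="stable"))
        assert np.array_equal(np.argsort(-only_pc.combined, kind="stable"),
                              np.argsort(-only_pc.pearson_scaled, kind="stable"))

    def test_tie_breaking_by_feature_index(self):
        s = combine_scores([1.0, 0.0], [0.0, 1.0], alpha=0.5)
        assert np.allclose(s.combined, [0.5, 0.5])
        assert s.rank.tolist() == [1, 2]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_scores([1.0], [0.5, 0.2])

    def test_select_all_and_empty_threshold(self, tiny_features):
        s = score_features(tiny_features, seed=0)
        assert set(select_top(s, k=4).tolist()) == {0, 1, 2, 3}
        with pytest.warns(UserWarning):
            assert select_top(s, threshold=2.0).size == 0

    def test_alpha_moves_ranking_monotonically(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 120)
        X = rng.normal(0, 1, (120, 8)) + 0.8 * y[:, None] * rng.normal(0, 1, 8)
        t = FeatureTable([f"f{i}" for i in range(8)], X, y)
        rf = relieff_weights(t, k_neighbors=5)
        pc = pearson_scores(t)
        relieff_rank = combine_scores(rf, pc, 1.0).rank
        corr = [spearmanr(combine_scores(rf, pc, a).rank, relieff_rank).statistic
                for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b >= a - 1e-12 for a, b in zip(corr, corr[1:]))

    def test_planted_signal_recovery(self):
        hits = 0
        for seed in range(8):
            t = sd.gen_patient_records(800, n_signal=5, n_noise=8, seed=seed)
            sig = {n for n, v in t.provenance.items() if v == "signal"}
            from cilad.features import extract_all
            table = extract_all("tabular", t)
            # drop the row-moment augmentation: score the raw predictors
            raw = FeatureTable(table.names[:13], table.values[:, :13], table.labels)
            scores = score_features(raw, seed=seed)
            top5 = {raw.names[j] for j in select_top(scores, k=5)}
            if len(top5 & sig) >= 4:
                hits += 1
        assert hits >= 6
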