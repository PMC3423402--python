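import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connmod import classification as clf
from connmod.exceptions import CompletenessError, ConfigError, InvalidArgumentError


def _labels(n0, n1):
    return np.array(["control"] * n0 + ["patient"] * n1)


class TestFeatureMatrix:
    def _tables(self, n_subjects, n_nodes, rng):
        tabs, pis = [], []
        for _ in range(n_subjects):
            tabs.append(
                pd.DataFrame(
                    rng.random((n_nodes, 7)),
                    columns=["degree", "strength", "BC", "CC", "LE", "GE", "LEGE"],
                )
            )
            pis.append(rng.random(n_nodes))
        return tabs, pis

    def test_column_count_and_naming(self):
        rng = np.random.default_rng(0)
        tabs, pis = self._tables(4, 95, rng)
        names = [f"R{i}" for i in range(95)]
        x, y = clf.build_feature_matrix(tabs, pis, _labels(2, 2), names)
        assert x.shape == (4, 760)
        assert x.columns[0] == "PI:R0"
        # column lookup returns that node's PI
        assert x.loc[0, "PI:R3"] == pytest.approx(pis[0][3])

    def test_identical_inputs_identical_rows(self):
        rng = np.random.default_rng(1)
        tabs, pis = self._tables(1, 10, rng)
        x, _ = clf.build_feature_matrix(tabs * 2, pis * 2, _labels(1, 1))
        np.testing.assert_array_equal(x.iloc[0].values, x.iloc[1].values)

    def test_missing_metric_rejected(self):
        rng = np.random.default_rng(2)
        tabs, pis = self._tables(2, 5, rng)
        tabs[1] = tabs[1].drop(columns=["BC"])
        with pytest.raises(CompletenessError):
            clf.build_feature_matrix(tabs, pis, _labels(1, 1))


def _mi_discrete(a, b):
    mi = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            p_ab = np.mean((a == va) & (b == vb))
            if p_ab > 0:
                mi += p_ab * np.log(p_ab / (np.mean(a == va) * np.mean(b == vb)))
    return mi


class TestMrmr:
    def test_label_copy_ranked_first_duplicate_not_second(self):
        rng = np.random.default_rng(3)
        y = _labels(10, 10)
        y01 = (y == "patient").astype(float)
        x = rng.normal(size=(20, 6))
        x[:, 2] = y01 * 2.0  # perfectly informative
        x[:, 4] = x[:, 2]  # exact duplicate: fully redundant
        order = clf.mrmr_rank(x, y, 4)
        assert order[0] in (2, 4)
        dup = 4 if order[0] == 2 else 2
        assert order[1] != dup

    def test_constant_feature_never_precedes_informative(self):
        rng = np.random.default_rng(4)
        y = _labels(8, 8)
        x = rng.normal(size=(16, 3))
        x[:, 0] = 1.0  # constant: zero information
        x[:, 1] = (y == "patient") + rng.normal(0, 0.1, 16)
        order = clf.mrmr_rank(x, y, 3)
        assert order.index(1) < order.index(0)

    def test_greedy_matches_exhaustive_mid_on_three_features(self):
        # with 3 features the greedy MID order is checkable by enumeration
        rng = np.random.default_rng(5)
        agreements = 0
        for _ in range(20):
            y = _labels(12, 12)
            y01 = (y == "patient").astype(float)
            x = rng.normal(size=(24, 3))
            x[:, 0] += y01 * rng.uniform(0.5, 2.0)
            x[:, 1] += y01 * rng.uniform(0.0, 1.0)
            order = clf.mrmr_rank(x, y, 3)
            disc = clf._discretize(x)
            rel = [_mi_discrete(disc[:, j], y01) for j in range(3)]
            first = int(np.argmax(rel))
            best_second, best_score = None, -np.inf
            for j in range(3):
                if j == first:
                    continue
                score = rel[j] - _mi_discrete(disc[:, j], disc[:, first])
                if score > best_score:
                    best_second, best_score = j, score
            if order[0] == first and order[1] == best_second:
                agreements += 1
        assert agreements == 20


class TestRfe:
    def test_informative_feature_survives_last(self):
        rng = np.random.default_rng(6)
        y = _labels(10, 10)
        x = rng.normal(size=(20, 2))
        x[:, 1] += (y == "patient") * 3.0
        order = clf.rfe_rank(x, y)
        assert order[0] == 1

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        y = _labels(8, 8)
        x = rng.normal(size=(16, 5))
        assert clf.rfe_rank(x, y) == clf.rfe_rank(x, y)


class TestMakeSplit:
    def test_half_split_sizes(self):
        labels = _labels(22, 21)
        for seed in range(10):
            s = clf.make_split(labels, seed)
            assert len(s.train_ids) in (21, 22)
            assert len(s.train_ids) + len(s.test_ids) == 43
            assert not set(s.train_ids) & set(s.test_ids)

    def test_accepted_splits_respect_band(self):
        labels = _labels(12, 12)
        y01 = (labels == "patient").astype(int)
        for seed in range(20):
            s = clf.make_split(labels, seed, balance_band=(0.45, 0.55))
            share = y01[s.train_ids].mean()
            assert 0.45 <= share <= 0.55

    def test_rejection_rate_matches_hypergeometric(self):
        # P(accept) for 12+12 subjects, train size 12, band [0.4, 0.6]:
        # patients in train must be 5, 6 or 7 of 12
        labels = _labels(12, 12)
        rng = np.random.default_rng(8)
        n_acc = int(stats.hypergeom(24, 12, 12).pmf([5, 6, 7]).sum() * 10000)
        rejections = [clf.make_split(labels, rng).n_rejected for _ in range(500)]
        # geometric mean rejections: (1-p)/p; compare observed acceptance rate
        p_acc = 1.0 / (1.0 + np.mean(rejections))
        assert p_acc == pytest.approx(n_acc / 10000, abs=0.1)

    def test_unsatisfiable_band_rejected(self):
        with pytest.raises(ConfigError):
            clf.make_split(_labels(20, 2), 0, balance_band=(0.45, 0.55), max_tries=200)


@pytest.fixture(scope="module")
def separable_toy():
    rng = np.random.default_rng(9)
    y = _labels(12, 12)
    x = rng.normal(size=(24, 30))
    x[12:, :3] += 8.0
    return x, y


class TestBaggedClassification:
    def test_separable_data_classified_perfectly(self, separable_toy):
        x, y = separable_toy
        rep = clf.bagged_classification(x, y, n_features=3, n_iterations=20,
                                        condition="actual", seed=0)
        assert rep.means["test_selectivity"] == pytest.approx(1.0)
        assert rep.means["test_sensitivity"] == pytest.approx(1.0)
        assert rep.means["train_selectivity"] == pytest.approx(1.0)

    def test_pre_shuffle_lands_at_chance(self, separable_toy):
        x, y = separable_toy
        rep = clf.bagged_classification(x, y, 3, 300, "pre_shuffle", seed=1)
        assert 0.45 <= rep.means["test_selectivity"] <= 0.55
        assert 0.45 <= rep.means["test_sensitivity"] <= 0.55

    def test_post_shuffle_training_equals_actual_training(self, separable_toy):
        x, y = separable_toy
        a = clf.bagged_classification(x, y, 3, 10, "actual", seed=2)
        b = clf.bagged_classification(x, y, 3, 10, "post_shuffle", seed=2)
        np.testing.assert_allclose(
            a.per_iteration["train_selectivity"], b.per_iteration["train_selectivity"]
        )

    def test_bit_reproducible(self, separable_toy):
        x, y = separable_toy
        a = clf.bagged_classification(x, y, 2, 1, "actual", seed=3)
        b = clf.bagged_classification(x, y, 2, 1, "actual", seed=3)
        pd.testing.assert_frame_equal(a.per_iteration, b.per_iteration)

    def test_unknown_condition_rejected(self, separable_toy):
        x, y = separable_toy
        with pytest.raises(InvalidArgumentError):
            clf.bagged_classification(x, y, 2, 1, "shuffled", seed=0)


class TestFeatureCountCurve:
    def test_single_k_equals_direct_call(self, separable_toy):
        x, y = separable_toy
        curve = clf.feature_count_curve(x, y, k_values=[4], n_iterations=5, seed=4)
        direct = clf.bagged_classification(x, y, 4, 5, "actual", seed=4)
        assert curve.loc[0, "test_selectivity"] == pytest.approx(
            direct.means["test_selectivity"]
        )
        assert len(curve) == 1

    def test_curve_length_matches_grid(self, separable_toy):
        x, y = separable_toy
        curve = clf.feature_count_curve(x, y, k_values=[1, 3, 5], n_iterations=3, seed=5)
        assert list(curve["n_features"]) == [1, 3, 5]


def test_metric_share_counts_family_membership():
    ranked = [0, 1, 95, 96, 200]
    assert clf.metric_share(ranked, n_nodes=95, metric="PI", top=5) == 2
    assert clf.metric_share(ranked, n_nodes=95, metric="degree", top=5) == 2
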