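import numpy as np
import pandas as pd
import pytest

from eegsense.features import FeatureTable
from eegsense.selection import (
    SpearmanFilter,
    embedded_l1,
    mann_whitney_u,
    permutation_test,
    rfe,
    spearman_filter,
    two_test_screen,
)


def _table(data: np.ndarray, labels: np.ndarray, bands=None) -> FeatureTable:
    n, p = data.shape
    bands = bands or ["gamma"] * p
    cols = pd.MultiIndex.from_tuples(
        [("ch0", bands[j], f"f{j}") for j in range(p)],
        names=["channel", "band", "feature"],
    )
    df = pd.DataFrame(data, columns=cols,
                      index=[f"s{i}" for i in range(n)])
    groups = pd.Series(["case" if l else "control" for l in labels],
                       index=df.index, name="group")
    return FeatureTable(df, groups)


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2, 3, 4])
        assert permutation_test(a, a.copy(), n_perm=999, seed=0) == 1.0

    def test_maximal_separation_gives_minimal_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.001, 10)
        b = rng.normal(100.0, 0.001, 10)
        p = permutation_test(a, b, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000, abs=2 / 1000)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 400
        for i in range(n_rep):
            x = rng.standard_normal(20)
            if permutation_test(x[:10], x[10:], n_perm=499, seed=i) < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        U, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert U == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 2, 3], [1.0, 2, 3])
        assert p > 0.9

    def test_exact_path_matches_label_enumeration(self):
        """For a=[1,2], b=[3,4]: 6 equally likely 2+2 label assignments,
        two of which (the observed one and its mirror) are as extreme."""
        from itertools import combinations

        vals = np.array([1.0, 2.0, 3.0, 4.0])
        u_obs, p = mann_whitney_u(vals[:2], vals[2:])
        extremeness = []
        for idx in combinations(range(4), 2):
            a = vals[list(idx)]
            b = np.delete(vals, list(idx))
            u, _ = mann_whitney_u(a, b)
            extremeness.append(min(u, 4 - u) <= min(u_obs, 4 - u_obs))
        assert p == pytest.approx(np.mean(extremeness))

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        # all splits of 8 distinct values into 4+4; the tie-corrected
        # normal approximation tracks enumeration to a few percent
        from itertools import combinations
        from scipy import stats

        vals = rng.standard_normal(8)
        for idx in combinations(range(8), 4):
            a = vals[list(idx)]
            b = np.delete(vals, list(idx))
            _, p_pkg = mann_whitney_u(a, b)  # exact path (n=8)
            p_asym = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_pkg - p_asym) < 0.05


class TestTwoTestScreen:
    def test_separated_feature_retained_noise_mostly_dropped(self, rng):
        n = 12
        labels = np.array([1] * 6 + [0] * 6)
        noise = rng.standard_normal((n, 200))
        signal = labels * 10.0 + rng.normal(0, 0.1, n)
        table = _table(np.column_stack([signal, noise]), labels)
        res = two_test_screen(table, alpha=0.05, n_perm=999, seed=0)
        keys = [k[2] for k in res.retained]
        assert "f0" in keys
        # the two tests are positively dependent, so the joint null
        # retention rate sits between alpha^2 and alpha
        false_pos = len([k for k in keys if k != "f0"])
        assert false_pos / 200 <= 0.05

    def test_alpha_zero_retains_nothing(self, rng):
        labels = np.array([1] * 4 + [0] * 4)
        table = _table(rng.standard_normal((8, 5)), labels)
        res = two_test_screen(table, alpha=0.0, n_perm=99, seed=0)
        assert res.retained == []

    def test_duplicated_feature_both_retained(self, rng):
        labels = np.array([1] * 6 + [0] * 6)
        sig = labels * 5.0 + rng.normal(0, 0.1, 12)
        table = _table(np.column_stack([sig, sig]), labels)
        res = two_test_screen(table, alpha=0.05, n_perm=999, seed=0)
        assert len(res.retained) == 2

    def test_single_group_rejected(self, rng):
        table = _table(rng.standard_normal((4, 3)), np.ones(4))
        with pytest.raises(ValueError):
            two_test_screen(table)

    def test_every_drop_has_a_reason(self, rng):
        labels = np.array([1] * 5 + [0] * 5)
        table = _table(rng.standard_normal((10, 8)), labels)
        res = two_test_screen(table, n_perm=199, seed=0)
        assert set(res.dropped) | set(res.retained) == set(table.data.columns)


class TestSpearmanFilter:
    def test_duplicate_column_drops_later(self, rng):
        x = rng.standard_normal(20)
        labels = np.array([1] * 10 + [0] * 10)
        table = _table(np.column_stack([x, x]), labels)
        res = spearman_filter(table)
        assert [k[2] for k in res.retained] == ["f0"]

    def test_monotone_transform_detected(self, rng):
        x = rng.standard_normal(20)
        labels = np.array([1] * 10 + [0] * 10)
        table = _table(np.column_stack([x, x ** 3]), labels)
        res = spearman_filter(table)
        assert [k[2] for k in res.retained] == ["f0"]

    def test_independent_columns_rarely_dropped(self, rng):
        labels = np.array([1] * 15 + [0] * 15)
        table = _table(rng.standard_normal((30, 12)), labels)
        res = spearman_filter(table)
        assert len(res.retained) >= 11  # < 10% of columns dropped

    def test_cross_band_pairs_ignored(self, rng):
        x = rng.standard_normal(20)
        labels = np.array([1] * 10 + [0] * 10)
        table = _table(np.column_stack([x, x]), labels,
                       bands=["gamma", "alpha"])
        res = spearman_filter(table)
        assert len(res.retained) == 2

    def test_constant_column_treated_as_uncorrelated(self, rng):
        data = np.column_stack([np.ones(20), rng.standard_normal(20)])
        filt = SpearmanFilter().fit(pd.DataFrame(data))
        assert filt.support_.all()


class TestRFEAndEmbedded:
    def _informative(self, rng, n=30):
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        informative = labels * 3.0 + rng.normal(0, 0.3, n)
        noise = rng.standard_normal((n, 2))
        return np.column_stack([informative, noise]), labels

    def test_rfe_keeps_informative_feature(self, rng):
        X, y = self._informative(rng)
        res = rfe(X, y, estimator="logistic", n_target=1)
        assert res.retained == [0]

    def test_rfe_identity_when_target_is_all(self, rng):
        X, y = self._informative(rng)
        res = rfe(X, y, estimator="svm", n_target=3)
        assert sorted(res.retained) == [0, 1, 2]

    def test_rfe_ranking_is_permutation(self, rng):
        X, y = self._informative(rng)
        res = rfe(X, y, estimator="tree", n_target=1)
        assert sorted(res.ranking.values()) == [1, 2, 3]

    def test_rfe_bad_target_rejected(self, rng):
        X, y = self._informative(rng)
        with pytest.raises(ValueError):
            rfe(X, y, n_target=4)

    def test_l1_penalty_dominance_empties_selection(self, rng):
        X, y = self._informative(rng)
        assert embedded_l1(X, y, strength=1e6).retained == []

    def test_l1_weak_penalty_keeps_everything(self, rng):
        X, y = self._informative(rng)
        assert len(embedded_l1(X, y, strength=1e-6).retained) == 3

    def test_l1_moderate_keeps_informative_drops_noise(self, rng):
        labels = np.array([1] * 20 + [0] * 20)
        informative = labels * 3.0 + rng.normal(0, 0.3, 40)
        noise = rng.standard_normal((40, 8))
        res = embedded_l1(np.column_stack([informative, noise]), labels,
                          strength=2.0)
        assert 0 in res.retained
        assert len([k for k in res.retained if k != 0]) <= 4

    def test_l1_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            embedded_l1(rng.standard_normal((6, 3)), np.ones(6))
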