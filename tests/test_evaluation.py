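"""Evaluation protocol: folds, AUC, confidence intervals, cutoffs."""

import numpy as np
import pytest
from scipy.stats import norm

from hfreadmit.evaluation import (SingleClassError, auc,
                                  auc_by_timeline_length,
                                  bootstrap_auc_ci, cv_auc_ci,
                                  make_folds, youden_cutoff)


def all_pairs_auc(scores, labels):
    """Brute-force Mann-Whitney U oracle (ties count 1/2)."""
    s = np.asarray(scores)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_value_with_tie_pair(self):
        scores = [0.2, 0.8, 0.5, 0.5]
        labels = [0, 1, 0, 1]
        assert auc(scores, labels) == pytest.approx(
            all_pairs_auc(scores, labels))

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)     # induce ties
            assert auc(s, y) == pytest.approx(all_pairs_auc(s, y),
                                              abs=1e-12)

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, 10_000)
        s = rng.random(10_000)
        assert auc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc([0.1, 0.9], [1, 1])


class TestFolds:
    def test_exact_stratification_small(self):
        labels = np.array([1] * 20 + [0] * 80)
        plan = make_folds(labels, seed=0)
        for _, _, te in plan.folds:
            assert labels[te].sum() == 4

    def test_partition_and_stratification_laws(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            labels = (rng.random(400) < 0.25).astype(int)
            plan = make_folds(labels, seed=seed)
            tests = [set(te.tolist()) for _, _, te in plan.folds]
            assert set().union(*tests) == set(range(400))
            for i in range(5):
                for j in range(i + 1, 5):
                    assert not tests[i] & tests[j]
                tr, va, te = plan.folds[i]
                assert not (set(tr) | set(va)) & set(te)
                assert abs(labels[te].mean() - labels.mean()) <= \
                    0.01 + 1.0 / len(te)

    def test_same_seed_identical_plan(self):
        labels = np.array([0, 1] * 60)
        a = make_folds(labels, seed=3)
        b = make_folds(labels, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            for xa, xb in zip(fa, fb):
                np.testing.assert_array_equal(xa, xb)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_folds([0, 1] * 10, seed=0)


class TestCvAucCi:
    def test_identical_folds_center_on_auc(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200) + 0.3 * y
        a = auc(s, y)
        cvauc, lo, hi = cv_auc_ci([s] * 5, [y] * 5)
        assert cvauc == pytest.approx(a)
        assert lo < a < hi

    def test_interval_width_shrinks_like_root_n(self, rng):
        def width(n):
            ws = []
            for _ in range(40):
                y = np.repeat([0, 1], n // 2)
                s = rng.normal(size=n) + y
                folds = np.array_split(rng.permutation(n), 5)
                _, lo, hi = cv_auc_ci([s[f] for f in folds],
                                      [y[f] for f in folds])
                ws.append(hi - lo)
            return np.mean(ws)

        ratio = width(400) / width(1600)
        assert ratio == pytest.approx(2.0, abs=0.3)

    def test_single_class_fold_rejected(self):
        with pytest.raises(SingleClassError):
            cv_auc_ci([[0.1, 0.9]] * 2, [[1, 1], [0, 1]])

    def test_agrees_with_bootstrap(self, rng):
        n = 1000
        y = np.repeat([0, 1], n // 2)
        s = rng.normal(size=n) + 0.8 * y
        folds = np.array_split(rng.permutation(n), 5)
        _, lo, hi = cv_auc_ci([s[f] for f in folds],
                              [y[f] for f in folds])
        _, blo, bhi = bootstrap_auc_ci(s, y, n_boot=2000, seed=1)
        assert (hi - lo) == pytest.approx(bhi - blo, rel=0.2)


class TestYouden:
    def test_perfectly_separated_cutoff(self):
        s = np.array([0.1, 0.2, 0.7, 0.9])
        y = np.array([0, 0, 1, 1])
        cutoff, sens, spec = youden_cutoff(s, y)
        assert cutoff == pytest.approx(0.7)     # smallest positive score
        assert sens == 1.0 and spec == 1.0

    def test_binormal_optimum_near_midpoint(self, rng):
        n = 40_000
        y = np.repeat([0, 1], n // 2)
        s = rng.normal(size=n) + y              # means 0 and 1, sd 1
        cutoff, sens, spec = youden_cutoff(s, y)
        assert cutoff == pytest.approx(0.5, abs=0.1)
        # J at the optimum matches 2*Phi(1/2) - 1
        j_expected = norm.cdf(0.5) - norm.cdf(-0.5)
        assert sens + spec - 1 == pytest.approx(j_expected, abs=0.03)

    def test_j_index_in_unit_interval(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            s = rng.random(50)
            _, sens, spec = youden_cutoff(s, y)
            assert 0.0 <= sens + spec - 1 <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            youden_cutoff([0.5, 0.6], [0, 0])


class TestAucByLength:
    def test_all_length_one_single_point(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.random(100) + y
        curve = auc_by_timeline_length(s, y, np.ones(100, dtype=int))
        assert len(curve) == 1
        assert curve.auc.iloc[0] == pytest.approx(auc(s, y))

    def test_final_point_equals_overall_auc(self, rng):
        y = rng.integers(0, 2, 300)
        s = rng.random(300) + 0.5 * y
        lengths = rng.integers(1, 5, 300)
        curve = auc_by_timeline_length(s, y, lengths)
        assert curve.auc.iloc[-1] == pytest.approx(auc(s, y))

    def test_single_class_bins_skipped(self):
        y = np.array([1, 1, 0, 1])
        s = np.array([0.9, 0.8, 0.1, 0.7])
        lengths = np.array([1, 1, 2, 2])
        curve = auc_by_timeline_length(s, y, lengths, cumulative=False)
        assert list(curve.length) == [2]
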