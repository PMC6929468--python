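from itertools import product

import numpy as np
import pytest

from ssipred.config import S4VMConfig
from ssipred.s4vm import (
    SeparatorCandidate,
    diversity_penalty,
    s3vm_objective,
    s4vm_predict,
    safe_label_assignment,
    sample_separators,
    select_representatives,
)
from ssipred.svm_core import train_supervised
from ssipred.synthetic import ToySpec, make_two_gaussians


def cand(y_hat, h=1.0):
    y_hat = np.asarray(y_hat, dtype=float)
    return SeparatorCandidate(y_hat=y_hat, f=np.zeros(len(y_hat)), h=h)


class TestObjective:
    def test_norm_term_only(self):
        assert s3vm_objective(2.0, 0, 0, 1, 0.1) == 1.0

    def test_weighted_hinge_sum(self):
        assert s3vm_objective(0.0, 3.0, 5.0, 1.0, 0.1) == pytest.approx(3.5)

    def test_decreasing_hinge_never_increases_h(self):
        base = s3vm_objective(1.0, 2.0, 4.0, 1.0, 0.1)
        assert s3vm_objective(1.0, 1.5, 4.0, 1.0, 0.1) <= base
        assert s3vm_objective(1.0, 2.0, 3.0, 1.0, 0.1) <= base

    def test_negative_hinge_rejected(self):
        with pytest.raises(ValueError):
            s3vm_objective(1.0, -0.1, 0.0, 1.0, 0.1)


class TestDiversityPenalty:
    def test_identical_pair_scores_one(self):
        y = [1, -1, 1, 1]
        assert diversity_penalty([y, y]) == 1.0

    def test_complementary_pair_scores_zero(self):
        y = np.array([1, -1, 1, 1])
        assert diversity_penalty([y, -y]) == 0.0

    def test_single_labeling_scores_zero(self):
        assert diversity_penalty([[1, -1]]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            diversity_penalty([[1, -1], [1, -1, 1]])


class TestSampling:
    def test_local_search_never_increases_h(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=20, sigma=0.3, seed=1))
        cands = sample_separators(ds, S4VMConfig(T=10, k_repr=3, restarts=10, seed=1))
        assert cands
        for c in cands:
            assert c.h <= c.h_start + 1e-9

    def test_all_candidates_balanced(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=18, sigma=0.5, seed=2))
        for c in sample_separators(ds, S4VMConfig(T=8, k_repr=2, restarts=8, seed=2)):
            assert int(c.y_hat.sum()) == ds.r

    def test_distinct_seeds_give_distinct_initialisations(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=30, sigma=0.5, seed=3))
        starts = []
        for s in range(10):
            rng = np.random.default_rng(s)
            perm = rng.permutation(ds.u)
            y0 = -np.ones(ds.u)
            y0[perm[: (ds.r + ds.u) // 2]] = 1
            starts.append(tuple(y0))
        assert len(set(starts)) >= 9

    def test_zero_candidates_requested_is_error(self):
        ds, _ = make_two_gaussians(ToySpec(seed=0))
        cfg = S4VMConfig(T=1, k_repr=1, restarts=1, seed=0)
        object.__setattr__(cfg, "T", 0)  # bypass config validation to hit the guard
        with pytest.raises(ValueError, match="T >= 1"):
            sample_separators(ds, cfg)


class TestRepresentatives:
    def test_k_equals_count_returns_unchanged(self):
        cands = [cand([1, -1, 1]), cand([-1, 1, -1])]
        assert select_representatives(cands, 2) == cands

    def test_two_tight_groups_yield_one_representative_each(self, rng):
        base1 = np.concatenate([np.ones(10), -np.ones(10)])
        base2 = -base1
        group1, group2 = [], []
        for i in range(5):
            y1, y2 = base1.copy(), base2.copy()
            j = rng.integers(20)
            y1[j] *= -1  # Hamming radius 1 around each center
            k = rng.integers(20)
            y2[k] *= -1
            group1.append(cand(y1, h=1.0 + i))
            group2.append(cand(y2, h=2.0 + i))
        reps = select_representatives(group1 + group2, 2, seed=0)
        assert len(reps) == 2
        centers = sorted(float(np.sign(r.y_hat @ base1)) for r in reps)
        assert centers == [-1.0, 1.0]  # one per group

    def test_output_size_is_k(self):
        cands = [cand(np.sign(np.sin(np.arange(6) + t)) + 0.5, h=t) for t in range(8)]
        cands = [cand(np.where(c.y_hat > 0, 1, -1), c.h) for c in cands]
        assert len(select_representatives(cands, 3, seed=1)) == 3

    def test_empty_candidates_is_error(self):
        with pytest.raises(ValueError):
            select_representatives([], 1)


class TestSafeAssignment:
    def test_unanimous_representatives_win(self):
        y = np.array([1, -1, 1, -1.0])
        reps = [cand(y), cand(y)]
        out = safe_label_assignment(reps, np.array([-1, -1, -1, -1.0]))
        np.testing.assert_array_equal(out, y)

    def test_baseline_only_representative_returns_baseline(self):
        y_svm = np.array([1, 1, -1.0])
        out = safe_label_assignment([cand(y_svm)], y_svm)
        np.testing.assert_array_equal(out, y_svm)

    def test_fully_disagreeing_representatives_fall_back_to_baseline(self):
        y1 = np.array([1, 1, 1, 1.0])
        reps = [cand(y1), cand(-y1)]
        out = safe_label_assignment(reps, y1)
        # any alternative that helps against one representative hurts against
        # the other, so the worst-case gain cannot beat the baseline's zero
        np.testing.assert_array_equal(out, y1)


class TestS4VMPredict:
    def test_beats_or_matches_supervised_on_benign_instance(self):
        ds, truth = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=40, sigma=0.1, seed=7))
        labels, _ = s4vm_predict(ds, S4VMConfig(T=20, k_repr=5, seed=7))
        sup = train_supervised(ds.X_l, ds.y)
        acc_s4vm = np.mean(labels == truth)
        acc_sup = np.mean(sup.predict(ds.X_u) == truth)
        assert acc_s4vm >= acc_sup

    def test_worst_case_gain_matches_exhaustive_search(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=8, sigma=0.4, seed=5))
        cfg = S4VMConfig(T=10, k_repr=3, restarts=10, max_flips=20, seed=5)
        cands = sample_separators(ds, cfg)
        reps = select_representatives(cands, cfg.k_repr, cfg.seed)
        y_svm = train_supervised(ds.X_l, ds.y).predict(ds.X_u).astype(float)

        def worst_gain(y):
            return min(float(y @ c.y_hat) - float(y_svm @ c.y_hat) for c in reps)

        y_star = safe_label_assignment(reps, y_svm)
        exhaustive_best = max(worst_gain(np.array(v, dtype=float))
                              for v in product([-1, 1], repeat=ds.u))
        assert worst_gain(y_star) <= exhaustive_best + 1e-9
        assert worst_gain(y_star) >= 0.0  # never worse than the baseline

    def test_safety_regression_over_overlapping_toys(self):
        # increasing cluster overlap: the safe labeling must not degrade the
        # supervised baseline by more than 0.02 on average
        sigmas = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        acc_s, acc_b = [], []
        for i in range(20):
            ds, truth = make_two_gaussians(
                ToySpec(n_labeled=2, n_unlabeled=40, sigma=sigmas[i % 7], seed=100 + i))
            labels, _ = s4vm_predict(ds, S4VMConfig(seed=100 + i))
            sup = train_supervised(ds.X_l, ds.y)
            acc_s.append(np.mean(labels == truth))
            acc_b.append(np.mean(sup.predict(ds.X_u) == truth))
        assert np.mean(acc_s) >= np.mean(acc_b) - 0.02

    def test_intermediate_labelings_balanced_and_h_logged(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=16, sigma=0.4, seed=9))
        labels, diag = s4vm_predict(ds, S4VMConfig(T=6, k_repr=2, restarts=6, seed=9))
        assert diag["n_candidates"] >= 1
        assert all(np.isfinite(h) for h in diag["candidate_h"])
        assert 0.0 <= diag["omega_representatives"] <= 1.0
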