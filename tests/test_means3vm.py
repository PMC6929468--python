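import numpy as np
import pytest

from ssipred.config import KernelConfig as KernelSpec
from ssipred.means3vm import (
    SemiDataset,
    assign_d_by_ranking,
    augmented_kernel,
    class_mean_counts,
    enumerate_optimal_d,
    estimate_r,
    means3vm_iter,
    means3vm_mkl,
    solve_given_d,
)
from ssipred.svm_core import gram_matrix, train_supervised
from ssipred.synthetic import ToySpec, make_two_gaussians

LINEAR = KernelSpec(kind="linear")


def toy_1d():
    """Two separated 1-D clusters, one label each, two unlabeled points."""
    X = np.array([[-2.0], [2.0], [1.8], [-1.9]])
    y = np.array([-1.0, 1.0])
    return SemiDataset(X=X, y=y, u=2, r=0)


class TestBalanceArithmetic:
    def test_even_split(self):
        assert class_mean_counts(0, 10) == (5, 5)

    def test_shifted_split(self):
        assert class_mean_counts(2, 10) == (6, 4)

    def test_parity_violation_is_error(self):
        with pytest.raises(ValueError, match="adjust r"):
            class_mean_counts(1, 10)

    def test_counts_sum_to_u(self):
        for r in (-4, -2, 0, 2, 4):
            up, um = class_mean_counts(r, 10)
            assert up + um == 10 and up - um == r


class TestEstimateR:
    def test_balanced_labels(self):
        assert estimate_r([1, -1, 1, -1], 10) == 0

    def test_all_positive_clips_to_u(self):
        assert estimate_r([1, 1, 1], 10) == 10

    def test_parity_adjusted_toward_zero(self):
        # u*(n+-n-)/l = 10*2/4 = 5, (5+10) odd -> round toward 0 gives 4
        assert estimate_r([1, 1, 1, -1], 10) == 4


class TestAugmentedKernel:
    def test_one_dimensional_hand_computation(self):
        # linear kernel: phi(x) = x, so every entry is a plain product
        X = np.array([[-2.0], [2.0], [3.0], [-1.0]])
        K_base = gram_matrix(X, LINEAR)
        d = np.array([1.0, 0.0])  # mean+ = x3 = 3, mean- = x4 = -1
        K = augmented_kernel(K_base, d, 1, 1, l=2)
        expected = np.array([
            [4.0, -4.0, -6.0, 2.0],
            [-4.0, 4.0, 6.0, -2.0],
            [-6.0, 6.0, 9.0, -3.0],
            [2.0, -2.0, -3.0, 1.0],
        ])
        np.testing.assert_allclose(K, expected)

    def test_mean_mean_entry_matches_expansion(self, rng):
        X = rng.normal(size=(8, 2))
        K_base = gram_matrix(X, KernelSpec(kind="rbf", gamma=0.5))
        d = np.array([1.0, 0, 1, 0, 1])
        u_plus, u_minus, l = 3, 2, 3
        K = augmented_kernel(K_base, d, u_plus, u_minus, l)
        K_uu = K_base[l:, l:]
        expected = sum(
            d[i] * d[j] * K_uu[i, j] for i in range(5) for j in range(5)
        ) / u_plus**2
        assert K[l, l] == pytest.approx(expected)

    def test_symmetry_for_random_d(self, rng):
        X = rng.normal(size=(10, 3))
        K_base = gram_matrix(X, KernelSpec(kind="rbf", gamma=0.2))
        d = np.zeros(6)
        d[rng.choice(6, 3, replace=False)] = 1
        K = augmented_kernel(K_base, d, 3, 3, l=4)
        np.testing.assert_allclose(K, K.T)

    def test_invalid_d_rejected(self):
        X = np.zeros((4, 1))
        K_base = gram_matrix(X, LINEAR)
        with pytest.raises(ValueError, match="Delta"):
            augmented_kernel(K_base, np.array([1.0, 1.0]), 1, 1, l=2)


class TestSolveGivenD:
    def test_true_assignment_separates_unlabeled(self):
        ds = toy_1d()
        model, _ = solve_given_d(ds, np.array([1.0, 0.0]), spec=LINEAR)
        f_u = model.decision_values(ds.X_u)
        assert f_u[0] > 0 and f_u[1] < 0

    def test_c2_zero_reduces_to_supervised(self):
        ds = toy_1d()
        model, obj = solve_given_d(ds, np.array([1.0, 0.0]), c1=1.0, c2=0.0, spec=LINEAR)
        sup = train_supervised(ds.X_l, ds.y, C=1.0, spec=LINEAR)
        assert obj == pytest.approx(sup.objective, abs=1e-6)

    def test_objective_invariant_under_unlabeled_permutation(self, rng):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=8, sigma=0.4, seed=1))
        d = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
        _, obj1 = solve_given_d(ds, d, spec=LINEAR)
        perm = rng.permutation(8)
        X2 = np.vstack([ds.X_l, ds.X_u[perm]])
        ds2 = SemiDataset(X=X2, y=ds.y, u=8, r=ds.r)
        _, obj2 = solve_given_d(ds2, d[perm], spec=LINEAR)
        assert obj1 == pytest.approx(obj2, rel=1e-6)


class TestRankingAssignment:
    def test_top_two_selected(self):
        np.testing.assert_array_equal(assign_d_by_ranking(np.array([0.9, -0.2, 0.5]), 2),
                                      [1, 0, 1])

    def test_ties_break_by_ascending_index(self):
        np.testing.assert_array_equal(assign_d_by_ranking(np.zeros(3), 1), [1, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_decision_values(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=12)
        u_plus = int(rng.integers(1, 12))
        d = assign_d_by_ranking(f, u_plus)
        assert d.sum() == u_plus
        for i in range(12):
            for j in range(12):
                if f[i] > f[j]:
                    assert d[i] >= d[j]


class TestSolvers:
    def test_iter_labels_well_separated_toy_perfectly(self):
        ds, truth = make_two_gaussians(ToySpec(n_labeled=1, n_unlabeled=40, sigma=0.1, seed=0))
        _, labels = means3vm_iter(ds)
        assert np.mean(labels == truth) == 1.0

    def test_mkl_labels_well_separated_toy_perfectly(self):
        ds, truth = make_two_gaussians(ToySpec(n_labeled=1, n_unlabeled=40, sigma=0.1, seed=0))
        _, labels = means3vm_mkl(ds)
        assert np.mean(labels == truth) == 1.0

    def test_balance_constraint_exact(self):
        for seed in range(3):
            ds, _ = make_two_gaussians(ToySpec(n_labeled=3, n_unlabeled=20, sigma=0.5, seed=seed))
            for solver in (means3vm_iter, means3vm_mkl):
                _, labels = solver(ds)
                assert labels.sum() == ds.r

    def test_iter_objective_monotone_nonincreasing(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=3, n_unlabeled=24, sigma=0.6, seed=7))
        model, _ = means3vm_iter(ds)
        hist = model.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_r_equals_u_labels_everything_positive(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=6, sigma=0.3, seed=2))
        ds = SemiDataset(X=ds.X, y=ds.y, u=6, r=6)
        _, labels = means3vm_iter(ds)
        assert (labels == 1).all()

    def test_mkl_single_active_kernel_equals_solve_given_d(self):
        # one generation: the MKL combination with a single kernel is degenerate
        ds = toy_1d()
        model, _ = means3vm_mkl(ds, max_generations=1, spec=LINEAR)
        assert len(model.ds) == 1
        np.testing.assert_allclose(model.mus, [1.0])
        direct, obj = solve_given_d(ds, model.ds[0], spec=LINEAR)
        assert model.objective == pytest.approx(obj, rel=1e-5)

    def test_mkl_mu_is_probability_vector(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=16, sigma=0.7, seed=3))
        model, _ = means3vm_mkl(ds)
        assert np.all(model.mus >= -1e-12)
        assert model.mus.sum() == pytest.approx(1.0)

    def test_zero_unlabeled_reduces_to_supervised(self, rng):
        X = np.vstack([rng.normal([1, 0], 0.2, (5, 2)), rng.normal([-1, 0], 0.2, (5, 2))])
        y = np.concatenate([np.ones(5), -np.ones(5)])
        ds = SemiDataset(X=X, y=y, u=0, r=0)
        sup = train_supervised(X, y, C=1.0)
        for solver in (means3vm_iter, means3vm_mkl):
            model, labels = solver(ds)
            assert labels.size == 0
            np.testing.assert_allclose(model.decision_values(X), sup.decision_values(X),
                                       atol=1e-6)


class TestExhaustiveOracle:
    def test_solvers_match_enumeration_on_tiny_instance(self):
        ds, _ = make_two_gaussians(ToySpec(n_labeled=2, n_unlabeled=8, sigma=0.35, seed=5))
        d_opt, obj_opt = enumerate_optimal_d(ds)
        _, lab_it = means3vm_iter(ds)
        _, lab_mk = means3vm_mkl(ds)
        _, obj_it = solve_given_d(ds, (lab_it > 0).astype(float))
        _, obj_mk = solve_given_d(ds, (lab_mk > 0).astype(float))
        scale = max(abs(obj_opt), 1e-9)
        assert obj_mk <= obj_opt * 1.05 + 1e-9 or (obj_mk - obj_opt) / scale <= 0.05
        assert obj_mk <= obj_it + 1e-9  # mkl labeling at least as good as iter's
        assert obj_it >= obj_opt - 1e-9  # enumeration is the true optimum
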