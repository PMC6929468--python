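"""Label-mean semi-supervised SVM (meanS3VM), solved two ways.

The method maximises the margin between the two *class means* of the
unlabeled data.  A binary vector d over the unlabeled points assigns u+ of
them to the positive mean and u- to the negative mean, with u+ = (r+u)/2 and
u- = (u-r)/2 fixed by the balance parameter r (the equilibrium constraint
sum sgn f(x_u) = r prevents collapse onto one class).  For a fixed d the
problem is a convex SVM over the l labeled points plus two virtual
mean-instances, solvable purely from the base kernel.  The outer search over
d is done either by alternating optimisation with a ranking update
(``means3vm_iter``) or by cutting-plane multiple-kernel learning over the
augmented kernels of the active d's (``means3vm_mkl``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import KernelConfig as KernelSpec
from .svm_core import (
    _bias_from_kkt,
    gram_matrix,
    resolve_gamma,
    solve_svm_dual,
    train_supervised,
)

log = logging.getLogger(__name__)


@dataclass
class SemiDataset:
    """Feature matrix with the first l rows labeled and the last u unlabeled."""

    X: np.ndarray
    y: np.ndarray  # labels of the first l rows, in {+1,-1}
    u: int
    r: int = 0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.l + self.u != len(self.X):
            raise ValueError("X must stack l labeled rows above u unlabeled rows")
        if self.l < 2 or len(np.unique(self.y)) < 2:
            raise ValueError("need at least one labeled sample per class")
        if self.u >= 1:
            class_mean_counts(self.r, self.u)  # validates |r| <= u and parity

    @property
    def l(self) -> int:
        return len(self.y)

    @property
    def X_l(self) -> np.ndarray:
        return self.X[: self.l]

    @property
    def X_u(self) -> np.ndarray:
        return self.X[self.l:]


def class_mean_counts(r: int, u: int) -> tuple[int, int]:
    """Sizes of the two unlabeled mean-classes: u+ = (r+u)/2, u- = (u-r)/2."""
    if u < 1:
        raise ValueError("need at least one unlabeled sample")
    if abs(r) > u:
        raise ValueError(f"|r| = {abs(r)} exceeds u = {u}")
    if (r + u) % 2 != 0:
        raise ValueError(
            f"(r+u) must be even so that u+ is an integer; got r={r}, u={u} — "
            "adjust r by 1"
        )
    return (r + u) // 2, (u - r) // 2


def estimate_r(y_l, u: int) -> int:
    """Balance parameter from the labeled class ratio: r ~ u (n+ - n-) / l.

    Parity is adjusted toward zero (ties at r=0 go to the labeled majority
    sign) and the result clipped to [-u, u].
    """
    y_l = np.asarray(y_l)
    n_pos = int((y_l > 0).sum())
    n_neg = int((y_l < 0).sum())
    l = len(y_l)
    r = int(np.rint(u * (n_pos - n_neg) / l))
    r = max(-u, min(u, r))
    if (r + u) % 2 != 0:
        if r > 0:
            r -= 1
        elif r < 0:
            r += 1
        else:
            r = 1 if n_pos >= n_neg else -1
    return r


def augmented_kernel(K_base: np.ndarray, d: np.ndarray, u_plus: int, u_minus: int,
                     l: int) -> np.ndarray:
    """The (l+2)x(l+2) kernel of the labeled points plus the two class means.

    Entry (l, .) is the positive mean (1/u+) sum_j d_j phi(x_{l+j}); entry
    (l+1, .) the negative mean over the complementary points — everything is
    computed from K_base by the kernel trick.
    """
    d = np.asarray(d, dtype=float)
    u = len(d)
    if K_base.shape != (l + u, l + u):
        raise ValueError("K_base must cover the l+u training points")
    if not np.all((d == 0) | (d == 1)) or int(d.sum()) != u_plus or u_plus + u_minus != u:
        raise ValueError("d must be binary with exactly u+ ones (d in Delta)")
    w_pos = d / u_plus if u_plus > 0 else np.zeros(u)
    w_neg = (1 - d) / u_minus if u_minus > 0 else np.zeros(u)
    K_ll = K_base[:l, :l]
    K_lu = K_base[:l, l:]
    K_uu = K_base[l:, l:]
    K = np.empty((l + 2, l + 2))
    K[:l, :l] = K_ll
    K[:l, l] = K_lu @ w_pos
    K[:l, l + 1] = K_lu @ w_neg
    K[l, :l] = K[:l, l]
    K[l + 1, :l] = K[:l, l + 1]
    K[l, l] = w_pos @ K_uu @ w_pos
    K[l + 1, l + 1] = w_neg @ K_uu @ w_neg
    K[l, l + 1] = K[l + 1, l] = w_pos @ K_uu @ w_neg
    return K


@dataclass
class MeanS3VMModel:
    """Decision function of a (possibly kernel-weighted) label-mean S3VM fit.

    Each active d contributes an augmented kernel with weight mu_t; the dual
    vector alpha (length l+2) is shared, as in the MKL formulation.
    """

    dataset: SemiDataset
    ds: list  # active label vectors d_t
    mus: np.ndarray  # kernel weights on the simplex
    alpha: np.ndarray  # length l+2
    b: float
    spec: KernelSpec
    gamma: float | None
    objective: float  # dual optimum of the (combined-kernel) problem
    generations: int = 0
    d_final: np.ndarray | None = None

    def decision_values(self, Xq: np.ndarray) -> np.ndarray:
        ds = self.dataset
        l, u = ds.l, ds.u
        u_plus, u_minus = class_mean_counts(ds.r, u)
        Kq_l = gram_matrix(ds.X_l, self.spec, np.asarray(Xq, float), gamma=self.gamma)
        Kq_u = gram_matrix(ds.X_u, self.spec, np.asarray(Xq, float), gamma=self.gamma)
        f = (self.alpha[:l] * self.dataset.y) @ Kq_l
        for mu, d in zip(self.mus, self.ds):
            w_pos = d / u_plus if u_plus > 0 else np.zeros(u)
            w_neg = (1 - d) / u_minus if u_minus > 0 else np.zeros(u)
            f = f + mu * (self.alpha[l] * (w_pos @ Kq_u) - self.alpha[l + 1] * (w_neg @ Kq_u))
        return f + self.b

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(Xq) >= 0, 1, -1)


def _augmented_solve(dataset: SemiDataset, K_aug: np.ndarray, c1: float, c2: float):
    """Solve the augmented dual for one (possibly mu-combined) kernel.

    Feasible set: sum alpha_i ytilde_i = 0; alpha_{l+1} + alpha_{l+2} = c2;
    0 <= alpha_i <= c1 for labeled i; 0 <= alpha_{l+1}, alpha_{l+2} <= c2.
    """
    l = dataset.l
    y_tilde = np.concatenate([dataset.y, [1.0, -1.0]])
    lin = np.concatenate([np.ones(l), [0.0, 0.0]])
    upper = np.concatenate([np.full(l, c1), [c2, c2]])
    sel = np.concatenate([np.zeros(l), [1.0, 1.0]])
    if c2 == 0:
        alpha, obj = solve_svm_dual(K_aug[:l, :l], dataset.y, np.full(l, c1))
        alpha = np.concatenate([alpha, [0.0, 0.0]])
    else:
        alpha, obj = solve_svm_dual(K_aug, y_tilde, upper, lin=lin, extra_eq=(sel, c2))
    f_nob = (alpha * y_tilde) @ K_aug
    eps = 1e-7 * c1
    free = (alpha[:l] > eps) & (alpha[:l] < c1 - eps)
    if free.any():
        b = float(np.mean(dataset.y[free] - f_nob[:l][free]))
    elif c2 > 0 and alpha[l] > 1e-9 and alpha[l + 1] > 1e-9:
        # both mean-margin constraints active: s_+ + b = rho, s_- + b = -rho
        b = float(-(f_nob[l] + f_nob[l + 1]) / 2)
    else:
        b = _bias_from_kkt(K_aug[:l, :l], dataset.y, alpha[:l], c1)
    return alpha, b, obj


def solve_given_d(dataset: SemiDataset, d, c1: float = 1.0, c2: float = 0.1,
                  spec: KernelSpec | None = None,
                  K_base: np.ndarray | None = None,
                  gamma: float | None = None) -> tuple[MeanS3VMModel, float]:
    """Solve the convex label-mean problem for a fixed assignment d.

    Returns the model and the optimal objective value (equal to the primal
    minimum 1/2||w||^2 + c1 sum xi - c2 rho by strong duality).
    """
    spec = spec or KernelSpec()
    d = np.asarray(d, dtype=float)
    u_plus, u_minus = class_mean_counts(dataset.r, dataset.u)
    if gamma is None:
        gamma = resolve_gamma(spec, dataset.X)
    if K_base is None:
        K_base = gram_matrix(dataset.X, spec, gamma=gamma)
    K_aug = augmented_kernel(K_base, d, u_plus, u_minus, dataset.l)
    alpha, b, obj = _augmented_solve(dataset, K_aug, c1, c2)
    model = MeanS3VMModel(dataset=dataset, ds=[d], mus=np.array([1.0]), alpha=alpha,
                          b=b, spec=spec, gamma=gamma, objective=obj, d_final=d)
    return model, obj


def assign_d_by_ranking(f_u: np.ndarray, u_plus: int) -> np.ndarray:
    """d_i = 1 for exactly the u+ largest decision values (ties: lowest index).

    This is the optimal assignment for fixed (w, b): if f(x_i) > f(x_j) then
    d_i >= d_j in some optimal d.
    """
    f_u = np.asarray(f_u, dtype=float)
    order = np.argsort(-f_u, kind="stable")
    d = np.zeros(len(f_u))
    d[order[:u_plus]] = 1.0
    return d


def _labels_from_d(d: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(d) > 0.5, 1, -1)


def _initial_d(dataset: SemiDataset, c1, spec, gamma, u_plus) -> np.ndarray:
    # fix gamma to the value resolved on the full X so all stages share one kernel
    spec_fixed = KernelSpec(kind=spec.kind, gamma=gamma) if spec.kind == "rbf" else spec
    sup = train_supervised(dataset.X_l, dataset.y, C=c1, spec=spec_fixed)
    return assign_d_by_ranking(sup.decision_values(dataset.X_u), u_plus)


def means3vm_iter(dataset: SemiDataset, c1: float = 1.0, c2: float = 0.1,
                  spec: KernelSpec | None = None, max_generations: int = 50
                  ) -> tuple[MeanS3VMModel, np.ndarray]:
    """Alternating optimisation: solve for fixed d, re-rank d, repeat.

    A d-update is accepted only if it does not increase the objective, so the
    objective is non-increasing across generations; the loop stops at a fixed
    point, a rejected update, or ``max_generations``.  Returned unlabeled
    labels come from the final d and hence satisfy sum sgn = r exactly.
    """
    spec = spec or KernelSpec()
    if dataset.u == 0:
        return train_supervised(dataset.X_l, dataset.y, C=c1, spec=spec), np.array([])
    gamma = resolve_gamma(spec, dataset.X)
    K_base = gram_matrix(dataset.X, spec, gamma=gamma)
    u_plus, _ = class_mean_counts(dataset.r, dataset.u)
    d = _initial_d(dataset, c1, spec, gamma, u_plus)
    best_model, best_obj = solve_given_d(dataset, d, c1, c2, spec, K_base, gamma)
    history = [best_obj]
    for gen in range(1, max_generations):
        d_new = assign_d_by_ranking(best_model.decision_values(dataset.X_u), u_plus)
        if np.array_equal(d_new, best_model.d_final):
            break
        model, obj = solve_given_d(dataset, d_new, c1, c2, spec, K_base, gamma)
        if obj > best_obj + 1e-9:
            break  # reject the update; keep the best fixed point found
        best_model, best_obj = model, obj
        history.append(obj)
    best_model.generations = len(history)
    best_model.objective = best_obj
    best_model.objective_history = history
    return best_model, _labels_from_d(best_model.d_final)


def _mkl_solve(dataset: SemiDataset, K_augs: list[np.ndarray], c1: float, c2: float,
               n_iter: int = 30, tol: float = 1e-6):
    """Min over simplex kernel weights of the max-alpha dual, by alternating
    the alpha-QP on the combined kernel with exponentiated-gradient mu steps."""
    t = len(K_augs)
    mus = np.full(t, 1.0 / t)
    y_tilde = np.concatenate([dataset.y, [1.0, -1.0]])
    prev = np.inf
    alpha = b = None
    for _ in range(n_iter):
        K_comb = sum(m * K for m, K in zip(mus, K_augs))
        alpha, b, obj = _augmented_solve(dataset, K_comb, c1, c2)
        if t == 1 or abs(prev - obj) < tol:
            break
        prev = obj
        ay = alpha * y_tilde
        S = np.array([0.5 * ay @ K @ ay for K in K_augs])
        scale = np.abs(S).max()
        if scale < 1e-12:
            break
        mus = mus * np.exp(S / scale)
        mus = mus / mus.sum()
    return mus, alpha, b, obj


def means3vm_mkl(dataset: SemiDataset, c1: float = 1.0, c2: float = 0.1,
                 spec: KernelSpec | None = None, max_generations: int = 50,
                 tol: float = 1e-3) -> tuple[MeanS3VMModel, np.ndarray]:
    """Cutting-plane multiple-kernel learning over augmented kernels.

    Starting from the supervised-ranking d, each generation solves the MKL
    dual over the active kernels {K^{d_t}}, then proposes the most violated
    new d by ranking the combined decision values; the loop stops when the
    proposal duplicates an active d, the improvement falls below ``tol``, or
    ``max_generations`` is reached.  Final labels are the ranking of the
    combined decision values, so sum sgn = r holds exactly.
    """
    spec = spec or KernelSpec()
    if dataset.u == 0:
        return train_supervised(dataset.X_l, dataset.y, C=c1, spec=spec), np.array([])
    gamma = resolve_gamma(spec, dataset.X)
    K_base = gram_matrix(dataset.X, spec, gamma=gamma)
    u_plus, u_minus = class_mean_counts(dataset.r, dataset.u)
    l = dataset.l
    d0 = _initial_d(dataset, c1, spec, gamma, u_plus)
    active = [d0]
    K_augs = [augmented_kernel(K_base, d0, u_plus, u_minus, l)]
    mus, alpha, b, obj = _mkl_solve(dataset, K_augs, c1, c2)
    gens = 1
    for gen in range(1, max_generations):
        model = MeanS3VMModel(dataset, active, mus, alpha, b, spec, gamma, obj)
        d_new = assign_d_by_ranking(model.decision_values(dataset.X_u), u_plus)
        if any(np.array_equal(d_new, d) for d in active):
            break
        active.append(d_new)
        K_augs.append(augmented_kernel(K_base, d_new, u_plus, u_minus, l))
        mus, alpha, b, new_obj = _mkl_solve(dataset, K_augs, c1, c2)
        gens += 1
        if abs(obj - new_obj) < tol:
            obj = new_obj
            break
        obj = new_obj
    model = MeanS3VMModel(dataset, active, mus, alpha, b, spec, gamma, obj,
                          generations=gens)
    d_final = assign_d_by_ranking(model.decision_values(dataset.X_u), u_plus)
    model.d_final = d_final
    return model, _labels_from_d(d_final)


def enumerate_optimal_d(dataset: SemiDataset, c1: float = 1.0, c2: float = 0.1,
                        spec: KernelSpec | None = None):
    """Exhaustive minimisation over all d in Delta (oracle; u <= ~12 only)."""
    from itertools import combinations

    spec = spec or KernelSpec()
    gamma = resolve_gamma(spec, dataset.X)
    K_base = gram_matrix(dataset.X, spec, gamma=gamma)
    u_plus, _ = class_mean_counts(dataset.r, dataset.u)
    best = (None, np.inf)
    for ones in combinations(range(dataset.u), u_plus):
        d = np.zeros(dataset.u)
        d[list(ones)] = 1.0
        _, obj = solve_given_d(dataset, d, c1, c2, spec, K_base, gamma)
        if obj < best[1]:
            best = (d, obj)
    return best
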