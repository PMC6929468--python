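"""Kernels and the soft-margin SVM dual used throughout the package.

The supervised SVM is the baseline learner and also the inner solver of the
semi-supervised methods.  All duals here are small convex QPs (the augmented
label-mean dual has only l+2 variables); they are solved with scipy's SLSQP
under one contract, which keeps the c2=0 reduction of the semi-supervised
solvers numerically exact against the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel

from .config import KernelConfig

KernelSpec = KernelConfig  # the config dataclass doubles as the kernel spec


def default_gamma(X: np.ndarray) -> float:
    """RBF width heuristic gamma = 1 / (d * var(X)), as in scikit-learn's 'scale'."""
    X = np.asarray(X, dtype=float)
    v = X.var()
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


def resolve_gamma(spec: KernelSpec, X: np.ndarray) -> float | None:
    if spec.kind == "linear":
        return None
    return spec.gamma if spec.gamma is not None else default_gamma(X)


def gram_matrix(X: np.ndarray, spec: KernelSpec, Y: np.ndarray | None = None,
                gamma: float | None = None) -> np.ndarray:
    """Kernel matrix k(X, Y) (Y defaults to X).

    For rbf, ``gamma`` overrides the spec (pass the value resolved on the
    training set so test-time evaluations use the same kernel).
    """
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("kernel inputs must be finite")
    if spec.kind == "linear":
        return linear_kernel(X, Y)
    g = gamma if gamma is not None else resolve_gamma(spec, X)
    return rbf_kernel(X, Y, gamma=g)


def solve_svm_dual(K: np.ndarray, y: np.ndarray, upper: np.ndarray,
                   lin: np.ndarray | None = None,
                   extra_eq: tuple[np.ndarray, float] | None = None,
                   tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Maximise  lin'a - 1/2 (a*y)' K (a*y)  s.t.  y'a = 0, 0 <= a <= upper,
    and optionally  c'a = rhs  (``extra_eq``).

    Returns (alpha, optimal objective value).  This is the one QP contract of
    the package; K is jittered by 1e-10 on the diagonal for conditioning.
    """
    n = len(y)
    y = np.asarray(y, dtype=float)
    upper = np.asarray(upper, dtype=float)
    lin = np.ones(n) if lin is None else np.asarray(lin, dtype=float)
    Q = (K + K.T) / 2 + 1e-10 * np.eye(n)
    Yo = np.outer(y, y)

    def neg_obj(a):
        return -(lin @ a) + 0.5 * a @ (Q * Yo) @ a

    def neg_grad(a):
        return -lin + (Q * Yo) @ a

    cons = [{"type": "eq", "fun": lambda a: y @ a, "jac": lambda a: y}]
    x0 = np.zeros(n)
    if extra_eq is not None:
        c, rhs = extra_eq
        c = np.asarray(c, dtype=float)
        cons.append({"type": "eq", "fun": lambda a: c @ a - rhs, "jac": lambda a: c})
        # feasible start: split rhs over the constrained coordinates, balancing y'a=0
        idx = np.nonzero(c)[0]
        if len(idx) and rhs > 0:
            pos = [i for i in idx if y[i] > 0]
            neg = [i for i in idx if y[i] < 0]
            if pos and neg:
                for i in pos:
                    x0[i] = rhs / (2 * len(pos))
                for i in neg:
                    x0[i] = rhs / (2 * len(neg))
    res = minimize(neg_obj, x0, jac=neg_grad, method="SLSQP",
                   bounds=[(0.0, float(u)) for u in upper], constraints=cons,
                   options={"maxiter": 1000, "ftol": tol})
    alpha = np.clip(res.x, 0.0, upper)
    return alpha, -neg_obj(alpha)


@dataclass
class SVMModel:
    """A trained soft-margin SVM in dual form."""

    X: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    b: float
    spec: KernelSpec
    C: float
    gamma: float | None = None  # resolved rbf width, frozen at fit time
    objective: float = 0.0      # dual optimum = primal optimum

    def decision_values(self, Xq: np.ndarray) -> np.ndarray:
        """f(x) = sum_i alpha_i y_i k(x_i, x) + b."""
        Xq = np.asarray(Xq, dtype=float)
        if Xq.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model {self.X.shape[1]}, query {Xq.shape[1]}"
            )
        Kq = gram_matrix(self.X, self.spec, Xq, gamma=self.gamma)
        return (self.alpha * self.y) @ Kq + self.b

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        f = self.decision_values(Xq)
        return np.where(f >= 0, 1, -1)


def _bias_from_kkt(K, y, alpha, C) -> float:
    """b from free support vectors (0 < alpha < C): y_i f(x_i) = 1."""
    f_nob = (alpha * y) @ K
    eps = 1e-7 * max(C, 1.0)
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        return float(np.mean(y[free] - f_nob[free]))
    # no free SV: b lies in the KKT interval; take its midpoint
    cand = y - f_nob
    lo_set = ((y > 0) & (alpha <= eps)) | ((y < 0) & (alpha >= C - eps))
    hi_set = ((y > 0) & (alpha >= C - eps)) | ((y < 0) & (alpha <= eps))
    lo = cand[lo_set].max() if lo_set.any() else -np.inf
    hi = cand[hi_set].min() if hi_set.any() else np.inf
    if np.isfinite(lo) and np.isfinite(hi):
        return float((lo + hi) / 2)
    return float(lo if np.isfinite(lo) else (hi if np.isfinite(hi) else 0.0))


def train_supervised(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                     spec: KernelSpec | None = None) -> SVMModel:
    """Fit the standard soft-margin SVM dual on labeled data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    spec = spec or KernelSpec()
    gamma = resolve_gamma(spec, X)
    K = gram_matrix(X, spec, gamma=gamma)
    alpha, obj = solve_svm_dual(K, y, np.full(len(y), C))
    b = _bias_from_kkt(K, y, alpha, C)
    return SVMModel(X=X, y=y, alpha=alpha, b=b, spec=spec, C=C, gamma=gamma,
                    objective=obj)


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    return model.decision_values(X)
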