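"""Safe semi-supervised SVM (S4VM).

With few labels and many unlabeled points there are usually several
plausible low-density separators, and committing to the wrong one can make a
semi-supervised learner *worse* than the plain SVM.  S4VM therefore (i)
samples many large-margin low-density separators by seeded local search over
balanced unlabeled labelings, (ii) compresses them to a few diverse
representatives via k-means on the labelings, and (iii) outputs the labeling
that maximises the worst-case gain over the supervised baseline across those
representatives — so on benign data it matches or beats the baseline, and it
hedges when the candidate boundaries disagree.

Inner SVM refits use scikit-learn's libsvm backend for speed; the S3VM
objective h is recomputed from the fitted duals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .config import KernelConfig as KernelSpec
from .config import S4VMConfig
from .means3vm import SemiDataset, class_mean_counts
from .svm_core import gram_matrix, resolve_gamma, train_supervised

log = logging.getLogger(__name__)


@dataclass
class SeparatorCandidate:
    """One sampled low-density separator."""

    y_hat: np.ndarray      # +-1 labeling of the unlabeled points
    f: np.ndarray          # decision values on all l+u points
    h: float               # S3VM objective of this separator
    h_start: float = np.nan  # objective of the random labeling it started from


def s3vm_objective(f_norm2: float, hinge_l: float, hinge_u: float,
                   C1: float, C2: float) -> float:
    """h(f, y_hat) = ||f||^2/2 + C1 * labeled hinge + C2 * unlabeled hinge."""
    if hinge_l < 0 or hinge_u < 0:
        raise ValueError("hinge sums must be non-negative")
    return 0.5 * f_norm2 + C1 * hinge_l + C2 * hinge_u


def diversity_penalty(labelings) -> float:
    """Mean over pairs of the squared agreement fraction: 1 iff all identical,
    0 for complementary pairs, 0 when there is a single labeling."""
    ys = [np.asarray(y) for y in labelings]
    if not ys:
        raise ValueError("need at least one labeling")
    n = len(ys[0])
    if any(len(y) != n for y in ys):
        raise ValueError("labelings must have equal length")
    if len(ys) == 1:
        return 0.0
    vals = []
    for i in range(len(ys)):
        for j in range(i + 1, len(ys)):
            agree = float(np.mean(ys[i] == ys[j]))
            vals.append(agree ** 2)
    return float(np.mean(vals))


def _fit_and_h(X, y_l, y_hat, C1, C2, spec, gamma, K=None):
    """Weighted SVM on labeled + pseudo-labeled points; return (f, h)."""
    l, u = len(y_l), len(y_hat)
    y_all = np.concatenate([y_l, y_hat])
    w = np.concatenate([np.ones(l), np.full(u, C2 / C1)])
    if len(np.unique(y_all)) < 2:
        return np.zeros(l + u), np.inf
    if K is None:
        K = gram_matrix(X, spec, gamma=gamma)
    clf = SVC(C=C1, kernel="precomputed", tol=1e-6)
    clf.fit(K, y_all, sample_weight=w)
    f = clf.decision_function(K)
    dc = clf.dual_coef_[0]
    sv = clf.support_
    f_norm2 = float(dc @ K[np.ix_(sv, sv)] @ dc)
    hinge = np.maximum(0.0, 1.0 - y_all * f)
    h = s3vm_objective(f_norm2, hinge[:l].sum(), hinge[l:].sum(), C1, C2)
    return f, h


def _local_search(K, y_l, y0, r, C1, C2, max_flips, n_pairs_try: int = 5):
    """Greedy descent on h over balanced pair flips.

    Each step refits the SVM, then tries flipping the most-misclassified
    (+ -> -) / (- -> +) pair suggested by the decision values; a flip is kept
    only if h strictly decreases.  h is non-increasing along the trajectory.
    """
    l = len(y_l)
    y_hat = y0.copy()
    f, h = _fit_and_h(None, y_l, y_hat, C1, C2, None, None, K=K)
    h_start = h
    for _ in range(max_flips):
        f_u = f[l:]
        pos = np.nonzero(y_hat > 0)[0]
        neg = np.nonzero(y_hat < 0)[0]
        if len(pos) == 0 or len(neg) == 0:
            break
        # candidates ordered by how badly each side is classified
        pos_order = pos[np.argsort(f_u[pos], kind="stable")]
        neg_order = neg[np.argsort(-f_u[neg], kind="stable")]
        improved = False
        for i, j in zip(pos_order[:n_pairs_try], neg_order[:n_pairs_try]):
            y_try = y_hat.copy()
            y_try[i], y_try[j] = -1, 1
            f_try, h_try = _fit_and_h(None, y_l, y_try, C1, C2, None, None, K=K)
            if h_try < h - 1e-12:
                y_hat, f, h = y_try, f_try, h_try
                improved = True
                break
        if not improved:
            break
    return SeparatorCandidate(y_hat=y_hat, f=f, h=h, h_start=h_start)


def sample_separators(dataset: SemiDataset, config: S4VMConfig,
                      spec: KernelSpec | None = None, c1: float = 1.0,
                      c2: float = 0.1) -> list[SeparatorCandidate]:
    """Sample up to T distinct low-density separators by seeded local search.

    Each restart draws a random balanced labeling (sum = r), descends on h by
    balanced pair flips, and the distinct results with smallest h are kept.
    One restart is warm-started from the supervised ranking.
    """
    if config.T < 1:
        raise ValueError("need T >= 1 candidate separators")
    spec = spec or KernelSpec()
    rng = np.random.default_rng(config.seed)
    l, u = dataset.l, dataset.u
    u_plus, _ = class_mean_counts(dataset.r, u)
    gamma = resolve_gamma(spec, dataset.X)
    K = gram_matrix(dataset.X, spec, gamma=gamma)

    inits = []
    sup = train_supervised(dataset.X_l, dataset.y, C=c1,
                           spec=KernelSpec(kind=spec.kind, gamma=gamma)
                           if spec.kind == "rbf" else spec)
    f_u0 = sup.decision_values(dataset.X_u)
    order = np.argsort(-f_u0, kind="stable")
    y_rank = -np.ones(u)
    y_rank[order[:u_plus]] = 1
    inits.append(y_rank.astype(int))
    for _ in range(max(0, config.restarts - 1)):
        perm = rng.permutation(u)
        y0 = -np.ones(u, dtype=int)
        y0[perm[:u_plus]] = 1
        inits.append(y0)

    candidates: list[SeparatorCandidate] = []
    seen = set()
    for y0 in inits:
        cand = _local_search(K, dataset.y, np.asarray(y0, float), dataset.r,
                             c1, c2, config.max_flips)
        key = tuple(int(v) for v in cand.y_hat)
        if key not in seen and np.isfinite(cand.h):
            seen.add(key)
            candidates.append(cand)
    candidates.sort(key=lambda c: c.h)
    return candidates[: config.T]


def select_representatives(candidates: list[SeparatorCandidate], k_repr: int,
                           seed: int = 0) -> list[SeparatorCandidate]:
    """k-means over the +-1 labeling vectors; per cluster keep the lowest-h member."""
    if not candidates:
        raise ValueError("no candidate separators to select from")
    if k_repr >= len(candidates):
        return list(candidates)
    Y = np.array([c.y_hat for c in candidates], dtype=float)
    km = KMeans(n_clusters=k_repr, n_init=10, max_iter=100, random_state=seed)
    assign = km.fit_predict(Y)
    reps = []
    for cl in range(k_repr):
        members = [c for c, a in zip(candidates, assign) if a == cl]
        if members:
            reps.append(min(members, key=lambda c: c.h))
    return reps


def _gain(a: np.ndarray, b: np.ndarray) -> float:
    """#agreements - #disagreements = a . b for +-1 vectors."""
    return float(np.dot(a, b))


def safe_label_assignment(representatives: list[SeparatorCandidate],
                          y_svm: np.ndarray) -> np.ndarray:
    """Worst-case-safe labeling of the unlabeled points.

    Over the candidate pool (representative labelings plus the supervised
    baseline), return the y maximising  min_t [gain(y, y_t) - gain(y_svm, y_t)];
    ties go to the baseline, so the output never has negative worst-case gain.
    """
    if not representatives:
        raise ValueError("need at least one representative separator")
    y_svm = np.asarray(y_svm, dtype=float)
    pool = [c.y_hat.astype(float) for c in representatives] + [y_svm]
    best_y, best_score = y_svm, 0.0  # baseline scores 0 by definition
    for y in pool:
        score = min(_gain(y, c.y_hat) - _gain(y_svm, c.y_hat) for c in representatives)
        if score > best_score + 1e-12:
            best_y, best_score = y, score
    return np.where(best_y >= 0, 1, -1)


def s4vm_predict(dataset: SemiDataset, config: S4VMConfig | None = None,
                 spec: KernelSpec | None = None, c1: float = 1.0,
                 c2: float = 0.1) -> tuple[np.ndarray, dict]:
    """Full S4VM pipeline: sample -> representatives -> safe assignment.

    Returns the +-1 labels on the unlabeled points and a diagnostics dict
    with all candidate objectives and the diversity of the representatives.
    """
    config = config or S4VMConfig()
    spec = spec or KernelSpec()
    sup = train_supervised(dataset.X_l, dataset.y, C=c1, spec=spec)
    y_svm = sup.predict(dataset.X_u)
    candidates = sample_separators(dataset, config, spec, c1, c2)
    reps = select_representatives(candidates, config.k_repr, config.seed)
    labels = safe_label_assignment(reps, y_svm)
    diagnostics = {
        "candidate_h": [c.h for c in candidates],
        "candidate_h_start": [c.h_start for c in candidates],
        "n_candidates": len(candidates),
        "omega_representatives": diversity_penalty([c.y_hat for c in reps]),
        "baseline_labels": y_svm,
    }
    return labels, diagnostics
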