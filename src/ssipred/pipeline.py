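"""End-to-end composition: complexes -> features -> learners -> metrics.

This is the glue the command-line interface and the experiment scripts call;
each stage lives in its own module and stays usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .config import RunConfig
from .evaluation import MetricReport, confusion, cross_validate, metrics
from .features import Standardizer, encode_chain
from .io_formats import FeatureVector
from .labeling import build_dataset
from .means3vm import SemiDataset, means3vm_iter, means3vm_mkl
from .s4vm import s4vm_predict
from .svm_core import train_supervised
from .synthetic import semidataset_from_labels

log = logging.getLogger(__name__)

METHODS = ("svm", "means3vm-iter", "means3vm-mkl", "s4vm")


def extract_features(complexes, conservation, cfg: RunConfig | None = None
                     ) -> list[FeatureVector]:
    """Labeled 264-dim feature vectors for every surface residue of each chain."""
    cfg = cfg or RunConfig()
    out = []
    for chain, partner in complexes:
        labeled = build_dataset([(chain, partner)], conservation,
                                threshold=cfg.surface_threshold,
                                cutoff=cfg.interface_cutoff_angstrom,
                                scale=cfg.max_asa_scale)
        out.extend(encode_chain(labeled, chain.residues, k=cfg.window_k))
        n_pos = sum(1 for lr in labeled if lr.label == 1)
        log.info("chain %s: %d surface residues, %d interface",
                 chain.chain_id, len(labeled), n_pos)
    return out


def feature_matrix(records: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([fv.values for fv in records], dtype=float)
    y = np.array([fv.label for fv in records], dtype=int)
    return X, y


def _weighted_svm_predict(X_l, y_l, X_u, y_u, X_test, cfg: RunConfig):
    """Inductive extension: SVM on labeled (C1) + pseudo-labeled (C2) points."""
    from sklearn.svm import SVC

    from .svm_core import gram_matrix, resolve_gamma

    X_all = np.vstack([X_l, X_u])
    y_all = np.concatenate([y_l, y_u])
    w = np.concatenate([np.ones(len(y_l)), np.full(len(y_u), cfg.c2 / cfg.c1)])
    gamma = resolve_gamma(cfg.kernel, X_all)
    K = gram_matrix(X_all, cfg.kernel, gamma=gamma)
    clf = SVC(C=cfg.c1, kernel="precomputed", tol=1e-6)
    clf.fit(K, y_all, sample_weight=w)
    Kt = gram_matrix(X_all, cfg.kernel, np.asarray(X_test, float), gamma=gamma)
    return np.where(clf.decision_function(Kt.T) >= 0, 1, -1)


def make_learner(method: str, cfg: RunConfig | None = None):
    """A callable (X_l, y_l, X_u, X_test) -> +-1 predictions on X_test.

    Semi-supervised methods use the unlabeled pool transductively and extend
    inductively to the test fold; the plain SVM ignores the pool.
    """
    cfg = cfg or RunConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")

    def _semidataset(X_l, y_l, X_u):
        from .means3vm import estimate_r

        u = len(X_u)
        r = estimate_r(y_l, u) if cfg.r == "auto" else int(cfg.r)
        return SemiDataset(X=np.vstack([X_l, X_u]), y=np.asarray(y_l, float), u=u, r=r)

    def learner(X_l, y_l, X_u, X_test):
        std = Standardizer().fit(np.vstack([X_l, X_u]) if len(X_u) else np.asarray(X_l))
        X_l_s = std.transform(np.asarray(X_l, float))
        X_u_s = std.transform(np.asarray(X_u, float)) if len(X_u) else np.empty((0, X_l_s.shape[1]))
        X_t_s = std.transform(np.asarray(X_test, float))
        if method == "svm" or len(X_u) == 0:
            model = train_supervised(X_l_s, y_l, C=cfg.c1, spec=cfg.kernel)
            return model.predict(X_t_s)
        ds = _semidataset(X_l_s, y_l, X_u_s)
        if method == "means3vm-iter":
            model, _ = means3vm_iter(ds, cfg.c1, cfg.c2, cfg.kernel, cfg.max_generations)
            return model.predict(X_t_s)
        if method == "means3vm-mkl":
            model, _ = means3vm_mkl(ds, cfg.c1, cfg.c2, cfg.kernel, cfg.max_generations)
            return model.predict(X_t_s)
        labels, _ = s4vm_predict(ds, cfg.s4vm, cfg.kernel, cfg.c1, cfg.c2)
        return _weighted_svm_predict(X_l_s, y_l, X_u_s, labels, X_t_s, cfg)

    return learner


def transductive_run(X, y, method: str, cfg: RunConfig | None = None,
                     seed: int | None = None) -> tuple[np.ndarray, np.ndarray, MetricReport]:
    """Mask a seeded fraction of labels, predict them, score against the truth.

    Returns (predictions on the unlabeled block, its truth, MetricReport).
    Standardization is fit on the full matrix (all rows are training data in
    the transductive setting).
    """
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    from .evaluation import mask_unlabeled

    y = np.asarray(y)
    mask = mask_unlabeled(y, cfg.unlabeled_fraction, rng)
    X_s = Standardizer().fit_transform(np.asarray(X, float))
    ds, truth = semidataset_from_labels(X_s, y, mask, r=cfg.r)
    if method == "svm":
        model = train_supervised(ds.X_l, ds.y, C=cfg.c1, spec=cfg.kernel)
        pred = model.predict(ds.X_u)
    elif method == "means3vm-iter":
        _, pred = means3vm_iter(ds, cfg.c1, cfg.c2, cfg.kernel, cfg.max_generations)
    elif method == "means3vm-mkl":
        _, pred = means3vm_mkl(ds, cfg.c1, cfg.c2, cfg.kernel, cfg.max_generations)
    elif method == "s4vm":
        s4cfg = replace(cfg.s4vm, seed=seed)
        pred, _ = s4vm_predict(ds, s4cfg, cfg.kernel, cfg.c1, cfg.c2)
    else:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    return pred, truth, metrics(confusion(pred, truth))


def evaluate_method(X, y, method: str, cfg: RunConfig | None = None) -> list[MetricReport]:
    """Stratified CV of one method under the configured unlabeled fraction."""
    cfg = cfg or RunConfig()
    return cross_validate(X, y, make_learner(method, cfg), folds=cfg.folds,
                          unlabeled_fraction=cfg.unlabeled_fraction, seed=cfg.seed)
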