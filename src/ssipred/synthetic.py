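"""Synthetic fixtures: 2-D semi-supervised toys, two-chain complexes with a
plantable conservation signal, and random confusion instances.

The complex generator emulates the statistical structure the pipeline
assumes: chain B sits in a compact blob; a chosen fraction of chain A's
surface residues is placed strictly inside the interface distance cutoff of
some B residue (with a 1 A guard band on both sides so planted labels are
robust to floating point), the rest strictly outside; interface residues
draw peaked Dirichlet profiles (low entropy), non-interface residues flat
ones, with the gap controlled by a single knob in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AA_ORDER, Chain, ResidueRecord
from .features import relative_entropy, sequence_entropy
from .labeling import max_asa
from .means3vm import SemiDataset, estimate_r


@dataclass(frozen=True)
class ToySpec:
    """Two-Gaussian semi-supervised toy problem."""

    n_labeled: int = 1          # per class
    n_unlabeled: int = 40       # total, split evenly between components
    center: tuple = (1.0, 0.0)  # components at +-center
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0 or self.n_labeled < 1:
            raise ValueError("need sigma > 0 and at least one label per class")


def make_two_gaussians(spec: ToySpec) -> tuple[SemiDataset, np.ndarray]:
    """Draw the toy dataset; returns (SemiDataset, truth on the unlabeled points).

    Points come from N(+-center, sigma^2 I); the labeled rows hold the first
    ``n_labeled`` draws of each component, and r is the true unlabeled balance.
    """
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.center, dtype=float)
    n_u_pos = spec.n_unlabeled // 2
    n_u_neg = spec.n_unlabeled - n_u_pos
    pos = rng.normal(c, spec.sigma, size=(spec.n_labeled + n_u_pos, 2))
    neg = rng.normal(-c, spec.sigma, size=(spec.n_labeled + n_u_neg, 2))
    X_l = np.vstack([pos[: spec.n_labeled], neg[: spec.n_labeled]])
    y_l = np.concatenate([np.ones(spec.n_labeled), -np.ones(spec.n_labeled)])
    X_u = np.vstack([pos[spec.n_labeled:], neg[spec.n_labeled:]])
    truth = np.concatenate([np.ones(n_u_pos), -np.ones(n_u_neg)])
    perm = rng.permutation(spec.n_unlabeled)
    X_u, truth = X_u[perm], truth[perm]
    r = int(truth.sum())
    ds = SemiDataset(X=np.vstack([X_l, X_u]), y=y_l, u=spec.n_unlabeled, r=r)
    return ds, truth


def _dirichlet_alpha(conservation_gap: float, interface: bool) -> float:
    """Dirichlet concentration per class; the gap knob interpolates
    alpha_interface from 2.0 (gap 0) down to 0.2 (gap 1) on a log scale."""
    if not interface:
        return 2.0
    return 2.0 * 10.0 ** (-conservation_gap)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_synthetic_complex(n_a: int = 60, n_b: int = 30,
                           interface_fraction: float = 0.3,
                           conservation_gap: float = 1.0,
                           surface_fraction: float = 0.8,
                           seed: int = 0):
    """Generate a two-chain complex with planted interface labels.

    Returns (chain_a, chain_b, conservation, truth) where ``conservation``
    maps chain_id -> (hssp_table, rate_table) and ``truth`` maps the
    seq_index of every planted *surface* residue of A to its +-1 label.
    Exactly ceil(interface_fraction * n_surface) surface residues of A lie
    strictly under 11 A from a B C-alpha; all other A residues lie beyond
    13 A, so the 12 A rule recovers the plant exactly.
    """
    if not (0 < interface_fraction < 1) or not (0 < surface_fraction <= 1):
        raise ValueError("fractions must lie in (0,1)")
    if conservation_gap < 0:
        raise ValueError("conservation_gap must be >= 0")
    rng = np.random.default_rng(seed)

    b_coords = rng.uniform(-6.0, 6.0, size=(n_b, 3))
    b_coords = b_coords[np.argsort(b_coords[:, 0], kind="stable")]

    n_surface = int(round(surface_fraction * n_a))
    n_interface = math.ceil(interface_fraction * n_surface)
    if n_interface < 1 or n_interface >= n_surface:
        raise ValueError("requested interface count is infeasible for this chain size")

    surface_flags = np.zeros(n_a, dtype=bool)
    surface_flags[rng.choice(n_a, size=n_surface, replace=False)] = True
    surface_idx = np.nonzero(surface_flags)[0]
    interface_set = set(rng.choice(surface_idx, size=n_interface, replace=False).tolist())

    far_center = np.array([60.0, 0.0, 0.0])  # comfortably outside the cutoff
    a_records, truth = [], {}
    hssp_a, rate_a = {}, {}
    for i in range(n_a):
        seq_index = i + 1
        aa = AA_ORDER[rng.integers(20)]
        is_interface = i in interface_set
        if is_interface:
            # within 10 A of one partner residue -> min distance < 11 A
            anchor = b_coords[rng.integers(n_b)]
            xyz = anchor + _random_unit(rng) * rng.uniform(4.0, 10.0)
            while np.min(np.linalg.norm(b_coords - xyz, axis=1)) >= 11.0:
                xyz = anchor + _random_unit(rng) * rng.uniform(4.0, 10.0)
        else:
            xyz = far_center + rng.uniform(-12.0, 12.0, size=3)
            # guard band: everything non-interface stays beyond 13 A
            while np.min(np.linalg.norm(b_coords - xyz, axis=1)) <= 13.0:
                xyz = far_center + rng.uniform(-12.0, 12.0, size=3)
        if surface_flags[i]:
            rsa = rng.uniform(0.25, 0.8)
            truth[seq_index] = 1 if is_interface else -1
        else:
            rsa = rng.uniform(0.0, 0.12)
        asa = rsa * max_asa(aa)

        alpha = _dirichlet_alpha(conservation_gap, is_interface and surface_flags[i])
        profile = rng.dirichlet(np.full(20, alpha))
        ent = sequence_entropy(profile)
        rel = relative_entropy(profile)
        hssp_a[seq_index] = {
            "profile": profile,
            "entropy": ent,
            "rel_entropy": rel,
            "weight": 1.0 - rel,
            "acc": asa,
        }
        rate_a[seq_index] = rel + rng.normal(0.0, 0.05)
        a_records.append(ResidueRecord("A", seq_index, aa, xyz, asa=asa))

    b_records, hssp_b, rate_b = [], {}, {}
    for j in range(n_b):
        seq_index = j + 1
        aa = AA_ORDER[rng.integers(20)]
        profile = rng.dirichlet(np.full(20, 2.0))
        rel = relative_entropy(profile)
        hssp_b[seq_index] = {
            "profile": profile,
            "entropy": sequence_entropy(profile),
            "rel_entropy": rel,
            "weight": 1.0 - rel,
            "acc": max_asa(aa) * 0.5,
        }
        rate_b[seq_index] = rel + rng.normal(0.0, 0.05)
        b_records.append(
            ResidueRecord("B", seq_index, aa, b_coords[j], asa=max_asa(aa) * 0.5)
        )

    chain_a = Chain("A", a_records)
    chain_b = Chain("B", b_records)
    conservation = {"A": (hssp_a, rate_a), "B": (hssp_b, rate_b)}
    return chain_a, chain_b, conservation, truth


def make_confusion_random(n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Independent fair +-1 prediction/truth vectors for metric oracles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pred = rng.choice([-1, 1], size=n)
    truth = rng.choice([-1, 1], size=n)
    return pred, truth


def semidataset_from_labels(X: np.ndarray, y: np.ndarray, unlabeled_mask,
                            r: int | str = "auto") -> tuple[SemiDataset, np.ndarray]:
    """Reorder (X, y) into a SemiDataset given a boolean unlabeled mask.

    Returns the dataset and the hidden truth of the unlabeled block.
    r="auto" estimates the balance parameter from the labeled class ratio.
    """
    unlabeled_mask = np.asarray(unlabeled_mask, dtype=bool)
    X_l, y_l = X[~unlabeled_mask], y[~unlabeled_mask]
    X_u, truth = X[unlabeled_mask], y[unlabeled_mask]
    u = len(X_u)
    r_val = estimate_r(y_l, u) if r == "auto" else int(r)
    ds = SemiDataset(X=np.vstack([X_l, X_u]), y=y_l, u=u, r=r_val)
    return ds, truth
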