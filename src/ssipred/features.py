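"""Evolutionary-conservation features and the spatial-window encoding.

Five per-residue features describe how conserved a sequence position is
across homologues: the 20-dimensional amino-acid profile (frequencies from a
multiple alignment), its Shannon entropy, the entropy normalised to [0,1]
(relative entropy), a conservation weight, and the evolutionary rate.  Each
target residue is encoded together with its 10 spatially closest chain
neighbours (by C-alpha distance), giving 11 blocks of 24 values = 264
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import (
    N_PER_RESIDUE,
    N_PROFILE,
    WINDOW_K,
    FeatureVector,
    ResidueRecord,
)

LOG2_20 = np.log2(N_PROFILE)

#: sentinel marking a padded window slot (short chains)
PAD = None


@dataclass
class ResidueFeatures:
    """The 24 conservation values of one residue."""

    profile: np.ndarray
    entropy: float
    rel_entropy: float
    cons_weight: float
    evo_rate: float

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (N_PROFILE,):
            raise ValueError("profile must have 20 entries")
        if abs(self.profile.sum() - 1.0) > 1e-9:
            raise ValueError("profile must sum to 1")
        if not 0 <= self.entropy <= LOG2_20 + 1e-9:
            raise ValueError("entropy out of range")

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [self.profile, [self.entropy, self.rel_entropy, self.cons_weight, self.evo_rate]]
        )


def profile_frequencies(raw) -> np.ndarray:
    """Normalise raw counts or percentages to frequencies summing to 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (N_PROFILE,):
        raise ValueError("profile must have 20 entries")
    if np.any(raw < 0):
        raise ValueError("profile entries must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("all-zero profile cannot be normalised")
    return raw / total


def sequence_entropy(profile, base: str = "bits") -> float:
    """Shannon entropy -sum p log p of a frequency profile (0 log 0 := 0)."""
    p = np.asarray(profile, dtype=float)
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h * np.log(2.0) if base == "nats" else h


def relative_entropy(profile) -> float:
    """Entropy normalised by its maximum log2(20): 0 = one amino acid, 1 = uniform."""
    return sequence_entropy(profile) / LOG2_20


def conservation_weight(hssp_weight, profile=None) -> float:
    """Per-position conservativeness: the HSSP WEIGHT when available.

    When no WEIGHT is carried, fall back to 1 - relative_entropy(profile) — a
    surrogate that, like the WEIGHT column, is high at conserved positions.
    """
    if hssp_weight is not None:
        return float(hssp_weight)
    if profile is None:
        raise ValueError("need either an HSSP weight or a profile")
    return 1.0 - relative_entropy(profile)


def residue_features(res: ResidueRecord) -> ResidueFeatures:
    """Bundle the five conservation features of one residue record."""
    if res.profile is None or res.evo_rate is None:
        raise ValueError(f"residue {res.seq_index}: conservation data incomplete")
    prof = profile_frequencies(res.profile)
    ent = res.entropy if res.entropy is not None else sequence_entropy(prof)
    rel = res.rel_entropy if res.rel_entropy is not None else relative_entropy(prof)
    return ResidueFeatures(prof, ent, rel, conservation_weight(res.cons_weight, prof),
                           res.evo_rate)


def _seq_key(idx):
    """Sortable key for seq_index: numeric order, insertion codes after."""
    if isinstance(idx, int):
        return (idx, "")
    s = str(idx)
    num = ""
    for ch in s:
        if ch.isdigit() or (ch == "-" and not num):
            num += ch
        else:
            break
    return (int(num) if num else 0, s[len(num):])


def spatial_window(target: ResidueRecord, pool: list[ResidueRecord],
                   k: int = WINDOW_K) -> list:
    """The k pool residues spatially closest to target, ascending distance.

    Ties break by ascending seq_index; slots beyond the pool size are padded
    with the PAD sentinel so the window always has length k.
    """
    others = [r for r in pool if r is not target]
    if not others:
        raise ValueError("window pool must contain at least one residue besides the target")
    d = cdist(target.ca_xyz[None, :], np.array([r.ca_xyz for r in others]))[0]
    order = sorted(range(len(others)), key=lambda i: (d[i], _seq_key(others[i].seq_index)))
    window = [others[i] for i in order[:k]]
    window += [PAD] * (k - len(window))
    return window


def assemble_vector(target_features: ResidueFeatures, neighbor_features: list,
                    chain_id: str = "", seq_index=0, label: int = 0,
                    k: int = WINDOW_K) -> FeatureVector:
    """Concatenate target + window blocks into the 264-dim feature vector.

    ``neighbor_features`` holds up to k ResidueFeatures (PAD entries allowed);
    padded slots contribute 24 zeros.
    """
    if len(neighbor_features) > k:
        raise ValueError(f"window holds at most {k} neighbours")
    blocks = [target_features.to_array()]
    for nf in list(neighbor_features) + [PAD] * (k - len(neighbor_features)):
        blocks.append(np.zeros(N_PER_RESIDUE) if nf is PAD else nf.to_array())
    return FeatureVector(chain_id, seq_index, label, np.concatenate(blocks))


class Standardizer:
    """Per-column z-scoring fit on the training fold and frozen.

    Padded 24-blocks (all-zero raw blocks — a real block's profile sums to 1,
    so it can never be all zero) stay zero after transformation: short-chain
    padding lives at the column origin of the standardized space rather than
    at the raw column means.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer must be fit first")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        n_blocks = X.shape[1] // N_PER_RESIDUE
        for b in range(n_blocks):
            sl = slice(b * N_PER_RESIDUE, (b + 1) * N_PER_RESIDUE)
            pad_rows = np.all(X[:, sl] == 0.0, axis=1)
            Z[pad_rows, sl] = 0.0
        return Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def encode_chain(labeled_residues, pool, k: int = WINDOW_K) -> list[FeatureVector]:
    """Build feature vectors for every labeled surface residue of one chain.

    ``pool`` is the full residue list of the chain (windowing uses all
    residues with coordinates, not only surface ones).
    """
    out = []
    for lr in labeled_residues:
        target = lr.record
        feats = residue_features(target)
        if k > 0:
            window = spatial_window(target, pool, k)
            nbr = [PAD if r is PAD else residue_features(r) for r in window]
        else:
            nbr = []
        fv = assemble_vector(feats, nbr, chain_id=target.chain_id,
                             seq_index=target.seq_index, label=lr.label, k=k)
        out.append(fv)
    return out
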