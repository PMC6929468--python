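"""Surface- and interface-residue definitions and dataset assembly.

A residue is a *surface* residue when its relative solvent accessibility
(ASA divided by the residue type's maximum ASA) exceeds a threshold
(default 16%, strict).  Among surface residues, an *interface* residue is
one whose C-alpha lies strictly within a distance cutoff (default 12 A,
i.e. 1.2 nm) of any C-alpha of the partner chain; other surface residues
are non-interface.  Buried residues stay unlabeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import Chain, ResidueRecord

log = logging.getLogger(__name__)

# Maximum accessible surface areas (A^2) per residue type.
# "rost_sander": Rost & Sander 1994. "tien2013": theoretical upper bounds of
# Tien et al. 2013.  Glycine is the minimum in both scales.
MAX_ASA_SCALES = {
    "rost_sander": {
        "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
        "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
        "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
        "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
    },
    "tien2013": {
        "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
        "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
        "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
        "S": 155.0, "T": 172.0, "W": 264.0, "Y": 263.0, "V": 174.0,
    },
}


@dataclass
class LabeledResidue:
    """A residue together with its surface flag and interface label.

    label: +1 interface, -1 non-interface, 0 unlabeled (buried residues only).
    """

    record: ResidueRecord
    is_surface: bool
    label: int

    def __post_init__(self):
        if self.label != 0 and not self.is_surface:
            raise ValueError("interface status is defined only among surface residues")


def max_asa(aa: str, scale: str = "rost_sander") -> float:
    """Maximum accessible surface area (A^2) for a canonical amino acid."""
    try:
        table = MAX_ASA_SCALES[scale]
    except KeyError:
        raise ValueError(f"unknown max-ASA scale {scale!r}") from None
    if aa not in table:
        raise ValueError(f"no maximum ASA for residue type {aa!r} (canonical 20 only)")
    return table[aa]


def is_surface(asa: float, aa: str, threshold: float = 0.16,
               scale: str = "rost_sander") -> bool:
    """True iff relative accessibility asa/max_asa(aa) strictly exceeds threshold."""
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    return asa / max_asa(aa, scale) > threshold


def label_interface(chain: Chain, partner: Chain, surface_mask,
                    cutoff: float = 12.0) -> list[LabeledResidue]:
    """Label every surface residue of ``chain`` by C-alpha proximity to ``partner``.

    +1 when the minimum C-alpha–C-alpha distance to *any* partner residue is
    strictly below ``cutoff`` (A); -1 otherwise.  Non-surface residues get 0.
    """
    if len(chain) == 0 or len(partner) == 0:
        raise ValueError("both chains must be non-empty")
    surface_mask = np.asarray(surface_mask, dtype=bool)
    if surface_mask.shape != (len(chain),):
        raise ValueError("surface_mask must align with chain residues")
    dmin = cdist(chain.coords(), partner.coords()).min(axis=1)
    out = []
    for res, surf, d in zip(chain.residues, surface_mask, dmin):
        if not surf:
            out.append(LabeledResidue(res, False, 0))
        else:
            out.append(LabeledResidue(res, True, 1 if d < cutoff else -1))
    return out


def _has_conservation(res: ResidueRecord) -> bool:
    return (
        res.profile is not None
        and res.entropy is not None
        and res.rel_entropy is not None
        and res.cons_weight is not None
        and res.evo_rate is not None
    )


def attach_conservation(chain: Chain, hssp_table: dict | None = None,
                        rate_table: dict | None = None) -> int:
    """Populate conservation fields from HSSP / Rate4Site tables in place.

    Returns the number of residues that received at least one new field.
    """
    hit = 0
    for res in chain.residues:
        touched = False
        if hssp_table is not None and res.seq_index in hssp_table:
            row = hssp_table[res.seq_index]
            res.profile = np.asarray(row["profile"], dtype=float)
            res.entropy = float(row["entropy"])
            res.rel_entropy = float(row["rel_entropy"])
            res.cons_weight = float(row["weight"])
            if res.asa is None and "acc" in row:
                res.asa = float(row["acc"])
            touched = True
        if rate_table is not None and res.seq_index in rate_table:
            res.evo_rate = float(rate_table[res.seq_index])
            touched = True
        hit += touched
    return hit


def build_dataset(complexes, conservation=None, threshold: float = 0.16,
                  cutoff: float = 12.0, scale: str = "rost_sander") -> list[LabeledResidue]:
    """Assemble labeled surface residues over a list of (chain, partner) pairs.

    ``conservation`` optionally maps chain_id -> (hssp_table, rate_table);
    tables are attached before filtering.  Residues that are nonstandard
    ('X'), lack ASA, or miss any of the five conservation inputs are dropped
    (the count is logged).  Only surface residues are returned.
    """
    out: list[LabeledResidue] = []
    n_dropped = 0
    for chain, partner in complexes:
        if conservation and chain.chain_id in conservation:
            hssp_table, rate_table = conservation[chain.chain_id]
            attach_conservation(chain, hssp_table, rate_table)
        mask = np.array(
            [
                res.aa != "X" and res.asa is not None
                and is_surface(res.asa, res.aa, threshold, scale)
                for res in chain.residues
            ]
        )
        labeled = label_interface(chain, partner, mask, cutoff)
        for lr in labeled:
            if not lr.is_surface:
                continue
            if lr.record.aa == "X" or not _has_conservation(lr.record):
                n_dropped += 1
                continue
            out.append(lr)
    if n_dropped:
        log.info("build_dataset: dropped %d surface residues lacking conservation data",
                 n_dropped)
    if not out:
        raise ValueError("dataset is empty: no surface residue had complete conservation data")
    return out
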