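"""Readers and writers for the formats the pipeline touches.

Inputs: PDB chains (C-alpha coordinates), per-residue conservation profiles in
the classic HSSP fixed-column profile block, and Rate4Site/ConSurf per-position
evolutionary rates.  Outputs: TSV feature tables and PDB files whose B-factor
column encodes the prediction category of each residue.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser

log = logging.getLogger(__name__)

#: canonical amino-acid order used for every 20-vector in this package
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: column order of the HSSP sequence-profile block
HSSP_AA_ORDER = "VLIMFWYGAPSTCHRKQEND"

N_PROFILE = 20
N_PER_RESIDUE = 24          # profile + entropy + rel_entropy + cons_weight + evo_rate
WINDOW_K = 10
N_FEATURES = N_PER_RESIDUE * (WINDOW_K + 1)  # 264


@dataclass
class ResidueRecord:
    """One residue with its C-alpha coordinate and conservation annotations.

    ``seq_index`` keeps the author numbering read from the file (insertion
    codes are appended, giving a string).  Conservation fields are ``None``
    until populated from HSSP / Rate4Site tables.
    """

    chain_id: str
    seq_index: int | str
    aa: str
    ca_xyz: np.ndarray
    asa: float | None = None
    profile: np.ndarray | None = None
    entropy: float | None = None
    rel_entropy: float | None = None
    cons_weight: float | None = None
    evo_rate: float | None = None

    def __post_init__(self):
        self.ca_xyz = np.asarray(self.ca_xyz, dtype=float)
        if self.ca_xyz.shape != (3,) or not np.all(np.isfinite(self.ca_xyz)):
            raise ValueError(f"residue {self.seq_index}: C-alpha must be 3 finite reals")
        if self.asa is not None and self.asa < 0:
            raise ValueError("ASA must be non-negative")
        if self.profile is not None:
            self.profile = np.asarray(self.profile, dtype=float)
            if self.profile.shape != (N_PROFILE,) or np.any(self.profile < 0):
                raise ValueError("profile must be 20 non-negative reals")


@dataclass
class Chain:
    """An ordered protein chain; residues sorted by ascending sequence position."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            if r.seq_index in seen:
                raise ValueError(f"duplicate seq_index {r.seq_index} in chain {self.chain_id}")
            seen.add(r.seq_index)

    def __len__(self):
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)


@dataclass
class FeatureVector:
    """264-value spatial-window encoding of one target residue.

    ``label`` is +1 (interface), -1 (non-interface) or 0 (unlabeled).
    """

    chain_id: str
    seq_index: int | str
    label: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.ndim == 1 and self.values.size
        if not n or n % N_PER_RESIDUE != 0:
            raise ValueError(
                f"feature vector length must be a positive multiple of {N_PER_RESIDUE} "
                f"(default {N_FEATURES}); got shape {self.values.shape}"
            )
        if self.label not in (-1, 0, 1):
            raise ValueError("label must be one of -1, 0, +1")


# ---------------------------------------------------------------------------
# PDB structures


def read_structure(path, chain_id: str) -> Chain:
    """Read one chain from a PDB file, one record per residue with a C-alpha.

    HETATM residues are skipped; nonstandard amino acids are kept with
    ``aa='X'`` so windowing geometry stays intact.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not present in {path}")
    records = []
    for res in model[chain_id]:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # HETATM
        if "CA" not in res:
            continue
        ca = res["CA"]
        if ca.is_disordered():
            ca = sorted(ca.disordered_get_list(), key=lambda a: a.get_altloc())[0]
        aa = protein_letters_3to1.get(res.get_resname().strip(), "X")
        if len(aa) != 1 or aa not in AA_ORDER:
            aa = "X"
        seq_index = resseq if not icode.strip() else f"{resseq}{icode.strip()}"
        records.append(ResidueRecord(chain_id, seq_index, aa, ca.get_coord()))
    if not records:
        raise ValueError(f"chain {chain_id!r} in {path} has no residues with a C-alpha atom")
    return Chain(chain_id, records)


def write_chain_pdb(chain: Chain, path, bfactors: dict | None = None) -> None:
    """Write the C-alpha trace of a chain as minimal PDB ATOM records."""
    one_to_three = {v: k for k, v in protein_letters_3to1.items() if len(v) == 1}
    with open(path, "w") as fh:
        for i, res in enumerate(chain.residues, 1):
            resname = one_to_three.get(res.aa, "UNK")
            num = res.seq_index if isinstance(res.seq_index, int) else int(str(res.seq_index)[:-1])
            b = 0.0 if bfactors is None else float(bfactors.get(res.seq_index, 0.0))
            x, y, z = res.ca_xyz
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:>3s} {chain.chain_id:1s}{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C\n"
            )
        fh.write("END\n")


_CATEGORY_CODE = {"TP": 1.0, "TN": 2.0, "FP": 3.0, "FN": 4.0}


def write_annotated_structure(chain: Chain, predictions: dict, path) -> None:
    """Write a PDB file whose B-factor encodes the prediction category.

    Codes: 1=TP, 2=TN, 3=FP, 4=FN, 0=not predicted — the textual analogue of
    colouring residues by outcome in a molecular viewer.
    """
    known = {r.seq_index for r in chain.residues}
    for idx in predictions:
        if idx not in known:
            raise ValueError(f"prediction for unknown residue index {idx!r}")
    codes = {}
    for idx, cat in predictions.items():
        if cat not in _CATEGORY_CODE:
            raise ValueError(f"unknown prediction category {cat!r}")
        codes[idx] = _CATEGORY_CODE[cat]
    write_chain_pdb(chain, path, bfactors=codes)


# ---------------------------------------------------------------------------
# HSSP conservation profiles


def write_hssp(path, rows: dict) -> None:
    """Write a conservation table in the classic HSSP profile-block dialect.

    ``rows`` maps seq_index -> dict with keys ``profile`` (20 frequencies in
    AA_ORDER), ``entropy``, ``rel_entropy`` (0..1), ``weight`` and optionally
    ``acc`` (solvent accessibility, A^2), which is appended as a trailing ACC
    column.  Used to build fixture files that exercise :func:`read_hssp`.
    """
    has_acc = any("acc" in row for row in rows.values())
    with open(path, "w") as fh:
        fh.write("HSSP       HOMOLOGY DERIVED SECONDARY STRUCTURE OF PROTEINS (synthetic)\n")
        fh.write("## SEQUENCE PROFILE AND ENTROPY\n")
        fh.write(
            " SeqNo PDBNo   " + "   ".join(HSSP_AA_ORDER)
            + "  NOCC NDEL NINS ENTROPY RELENT WEIGHT"
            + ("    ACC" if has_acc else "") + "\n"
        )
        for i, (idx, row) in enumerate(sorted(rows.items(), key=lambda kv: str(kv[0])), 1):
            prof = np.asarray(row["profile"], dtype=float)
            pct = [int(round(100 * prof[AA_INDEX[a]])) for a in HSSP_AA_ORDER]
            line = (
                f"{i:6d} {str(idx):>5s} " + " ".join(f"{p:3d}" for p in pct)
                + f"  {100:4d} {0:4d} {0:4d} {row['entropy']:7.3f}"
                + f" {int(round(100 * row['rel_entropy'])):6d} {row['weight']:6.2f}"
            )
            if has_acc:
                line += f" {row.get('acc', 0.0):6.1f}"
            fh.write(line + "\n")
        fh.write("//\n")


def read_hssp(path) -> dict:
    """Parse the per-residue profile block of an HSSP file.

    Returns seq_index -> dict(profile 20-vector of frequencies in AA_ORDER,
    entropy, rel_entropy in [0,1], weight).  A row whose 20 percentages sum to
    zero is flagged with a warning and replaced by a uniform profile.
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith("## SEQUENCE PROFILE"):
            start = i
            break
    if start is None:
        raise ValueError(f"{path}: no '## SEQUENCE PROFILE' block found")
    header = lines[start + 1].split()
    if len(header) < 22 or header[0] != "SeqNo":
        raise ValueError(f"{path}: malformed profile-block header")
    has_acc = header[-1] == "ACC"
    aa_cols = header[2:22]
    if "".join(aa_cols) != HSSP_AA_ORDER:
        raise ValueError(f"{path}: unexpected amino-acid column order {''.join(aa_cols)!r}")

    table: dict = {}
    for line in lines[start + 2:]:
        if line.startswith("//") or line.startswith("##"):
            break
        parts = line.split()
        if len(parts) < 28:
            continue
        pdbno = parts[1]
        try:
            key: int | str = int(pdbno)
        except ValueError:
            key = pdbno  # insertion code kept as string
        pct = np.array([float(p) for p in parts[2:22]])
        entropy = float(parts[25])
        relent = float(parts[26]) / 100.0
        weight = float(parts[27])
        if pct.sum() == 0:
            warnings.warn(f"{path}: position {pdbno} has an all-zero profile; using uniform")
            freq = np.full(N_PROFILE, 1.0 / N_PROFILE)
        else:
            freq = np.zeros(N_PROFILE)
            for a, p in zip(HSSP_AA_ORDER, pct):
                freq[AA_INDEX[a]] = p / 100.0
        table[key] = {
            "profile": freq,
            "entropy": entropy,
            "rel_entropy": min(max(relent, 0.0), 1.0),
            "weight": weight,
        }
        if has_acc and len(parts) >= 29:
            table[key]["acc"] = float(parts[28])
    if not table:
        raise ValueError(f"{path}: profile block contains no residue rows")
    return table


# ---------------------------------------------------------------------------
# Rate4Site / ConSurf scores


def write_rate4site(path, scores: dict, aas: dict | None = None) -> None:
    """Write per-position evolutionary rates in Rate4Site plain-text layout."""
    with open(path, "w") as fh:
        fh.write("# rates (synthetic)\n# POS SEQ SCORE\n")
        for idx in sorted(scores, key=str):
            aa = (aas or {}).get(idx, "A")
            fh.write(f"{idx} {aa} {scores[idx]: .4f}\n")


def read_rate4site(path) -> dict:
    """Parse Rate4Site/ConSurf per-position scores: seq_index -> rate."""
    rates: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            try:
                key: int | str = int(parts[0])
            except ValueError:
                key = parts[0]
            try:
                rates[key] = float(parts[2])
            except ValueError:
                continue
    if not rates:
        raise ValueError(f"{path}: no parseable rate rows")
    return rates


# ---------------------------------------------------------------------------
# TSV feature tables


def write_feature_table(records: list[FeatureVector], path, n_features: int = N_FEATURES,
                        header_comment: str | None = None) -> None:
    """Write feature vectors as TSV: chain_id, seq_index, label, f1..f264.

    All records must share one feature length (264 unless the window size was
    changed).  ``header_comment`` lines (run metadata) are prefixed with '#'.
    """
    if records:
        n_features = records[0].values.size
        if any(fv.values.size != n_features for fv in records):
            raise ValueError("all feature vectors must have the same length")
    cols = ["chain_id", "seq_index", "label"] + [f"f{i}" for i in range(1, n_features + 1)]
    rows = [[fv.chain_id, fv.seq_index, fv.label] + list(fv.values) for fv in records]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> list[FeatureVector]:
    """Read a TSV feature table back into FeatureVector records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    n_features = len(df.columns) - 3
    expected = ["chain_id", "seq_index", "label"] + [f"f{i}" for i in range(1, n_features + 1)]
    if n_features <= 0 or n_features % N_PER_RESIDUE != 0 or list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns chain_id, seq_index, label, f1..fN with N a "
            f"multiple of {N_PER_RESIDUE} (default {N_FEATURES}); found {len(df.columns)} columns"
        )
    out = []
    for _, row in df.iterrows():
        idx = row["seq_index"]
        if isinstance(idx, float) and math.isfinite(idx) and idx == int(idx):
            idx = int(idx)
        out.append(
            FeatureVector(
                chain_id=str(row["chain_id"]),
                seq_index=idx,
                label=int(row["label"]),
                values=row[expected[3:]].to_numpy(dtype=float),
            )
        )
    return out
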