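"""Run configuration: one flat namespace covering every pipeline stage.

The file format is plain ``key = value`` lines with optional ``[section]``
headers; a key inside ``[kernel]`` becomes ``kernel.key``.  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class KernelConfig:
    kind: str = "rbf"  # "rbf" or "linear"
    gamma: float | None = None  # None -> 1 / (d * var(X))

    def __post_init__(self):
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class S4VMConfig:
    T: int = 20          # number of candidate separators kept
    k_repr: int = 5      # representatives selected by k-means
    M: float = 1e4       # diversity constant of the sampling objective
    restarts: int = 30   # random initialisations of the local search
    max_flips: int = 50  # improving pair-flips allowed per restart
    seed: int = 0

    def __post_init__(self):
        if not (self.T >= self.k_repr >= 1):
            raise ValueError("need T >= k_repr >= 1")
        if self.M <= 0:
            raise ValueError("M must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Defaults follow the study conditions: C1=1, C2=0.1, 50 generations,
    surface threshold 16% relative ASA, interface cutoff 1.2 nm (12 A)."""

    surface_threshold: float = 0.16
    interface_cutoff_angstrom: float = 12.0
    max_asa_scale: str = "rost_sander"
    window_k: int = 10
    entropy_base: str = "bits"  # "bits" or "nats"
    kernel: KernelConfig = field(default_factory=KernelConfig)
    c1: float = 1.0
    c2: float = 0.1
    max_generations: int = 50
    r: int | str = "auto"  # "auto" -> estimate from labeled class balance
    folds: int = 5
    unlabeled_fraction: float = 0.7
    seed: int = 0
    s4vm: S4VMConfig = field(default_factory=S4VMConfig)

    def __post_init__(self):
        if not 0 < self.surface_threshold < 1:
            raise ValueError("surface_threshold must be in (0,1)")
        if self.interface_cutoff_angstrom <= 0:
            raise ValueError("interface cutoff must be positive")
        if self.entropy_base not in ("bits", "nats"):
            raise ValueError("entropy_base must be 'bits' or 'nats'")
        if self.c1 <= 0 or self.c2 < 0:
            raise ValueError("need c1 > 0 and c2 >= 0")
        if not 0 <= self.unlabeled_fraction < 1:
            raise ValueError("unlabeled_fraction must be in [0,1)")

    def hash(self) -> str:
        """Stable short hash of the full configuration (logged with outputs)."""
        blob = json.dumps(_as_flat_dict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_flat_dict(cfg) -> dict:
    out = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if hasattr(v, "__dataclass_fields__"):
            for k, sub in _as_flat_dict(v).items():
                out[f"{f.name}.{k}"] = sub
        else:
            out[f.name] = v
    return out


_SUBSECTIONS = {"kernel": KernelConfig, "s4vm": S4VMConfig}


def _coerce(cls, name: str, raw: str):
    ftype = {f.name: f.type for f in fields(cls)}[name]
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    if "str" in ftype and "int" not in ftype:
        return raw
    if "int | str" in ftype:
        try:
            return int(raw)
        except ValueError:
            return raw
    if "bool" in ftype:
        return raw.lower() in ("1", "true", "yes")
    if "int" in ftype:
        return int(raw)
    return float(raw)


def load_config(path) -> RunConfig:
    """Parse a key=value config file into a validated RunConfig."""
    top: dict = {}
    subs: dict[str, dict] = {k: {} for k in _SUBSECTIONS}
    section = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip()
                if section not in _SUBSECTIONS:
                    raise ValueError(f"unknown config section [{section}] (line {lineno})")
                continue
            if "=" not in line:
                raise ValueError(f"expected key = value at line {lineno}: {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            if "." in key:
                sec, key = key.split(".", 1)
                if sec not in _SUBSECTIONS:
                    raise ValueError(f"unknown config key {sec}.{key}")
                subs[sec][key] = raw
            elif section is not None:
                subs[section][key] = raw
            else:
                top[key] = raw

    kwargs = {}
    valid_top = {f.name for f in fields(RunConfig)}
    for key, raw in top.items():
        if key not in valid_top or key in _SUBSECTIONS:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = _coerce(RunConfig, key, raw)
    for sec, cls in _SUBSECTIONS.items():
        valid = {f.name for f in fields(cls)}
        sub_kwargs = {}
        for key, raw in subs[sec].items():
            if key not in valid:
                raise ValueError(f"unknown config key {sec}.{key}")
            sub_kwargs[key] = _coerce(cls, key, raw)
        if sub_kwargs:
            kwargs[sec] = cls(**sub_kwargs)
    return RunConfig(**kwargs)


def with_seed(cfg: RunConfig, seed: int) -> RunConfig:
    """Rebind the top-level seed, propagating a derived seed to the S4VM block."""
    return replace(cfg, seed=seed, s4vm=replace(cfg.s4vm, seed=seed * 7919 % (2**31)))
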