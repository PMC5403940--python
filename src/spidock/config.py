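"""Flat run configuration: defaults, key=value file parsing, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config", "parse_overrides"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults; unknown keys rejected.

    Geometry defaults give a 128x128 detector whose edge reaches the 4 A
    resolution cutoff at 1 A wavelength.  The experimental-data defaults are
    1,000 patterns photon-scaled to one photon per pixel in the 4 A shell,
    with orientations drawn per-angle-uniform inside the +-22.5 degree
    confined subspace.
    """

    # geometry
    wavelength: float = 1.0          # Angstrom
    distance: float = 100.0          # mm
    pixel_size: float = 0.45         # mm
    n_fast: int = 128
    n_slow: int = 128
    d_min: float = 4.0               # Angstrom, resolution cutoff

    # experimental-pattern simulation
    n_patterns: int = 1000
    d_target: float = 4.0            # photon-budget shell
    shell_frac: float = 0.05
    poisson: bool = True
    snr: float | None = None         # None = no Gaussian background
    seed: int = 0
    orientation_mode: str = "per_angle"   # or "so3"
    confine: bool = True             # restrict angles to the subspace below
    confine_half_deg: float = 22.5

    # decoy generation
    n_decoys: int = 60
    rot_max: float = 10.0            # degrees
    trans_max: float = 8.0           # Angstrom

    # orientation grid / matching
    grid_step: float = 3.0           # degrees
    representation: str = "raw"      # raw | ac | radial

    # scoring
    score_mode: str = "matched"      # matched | matching
    n_qbins: int = 32
    n_phibins: int = 72
    with_s_score: bool = False
    s_rot_step: float = 30.0
    n_select: str = "25,100,all"
    bins: int = 25

    def __post_init__(self) -> None:
        if self.representation not in ("raw", "ac", "radial"):
            raise ValueError(f"representation must be raw|ac|radial, got "
                             f"{self.representation!r}")
        if self.score_mode not in ("matched", "matching"):
            raise ValueError("score_mode must be matched|matching")
        if self.orientation_mode not in ("per_angle", "so3"):
            raise ValueError("orientation_mode must be per_angle|so3")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive or unset")

    # -- derived helpers ---------------------------------------------------
    def bounds(self):
        if not self.confine:
            return None
        h = self.confine_half_deg
        return ((-h, h), (-h, h), (-h, h))

    def n_select_list(self):
        out = []
        for tok in str(self.n_select).split(","):
            tok = tok.strip()
            out.append(None if tok in ("all", "") else int(tok))
        return out

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_BOOL_TRUE = {"1", "true", "yes", "on"}
_BOOL_FALSE = {"0", "false", "no", "off"}


def _coerce(name: str, typ, raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", "null"):
        return None
    if typ is bool or "bool" in str(typ):
        low = raw.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ValueError(f"cannot parse boolean for {name!r}: {raw!r}")
    if typ is int or typ == "int":
        return int(raw)
    if typ is float or "float" in str(typ):
        return float(raw)
    return raw


def parse_overrides(pairs, base: RunConfig | None = None) -> RunConfig:
    """Apply 'key=value' strings on top of a base config; unknown keys error."""
    cfg = asdict(base or RunConfig())
    types = {f.name: f.type for f in fields(RunConfig)}
    for pair in pairs:
        if "=" not in pair:
            raise ValueError(f"override must be key=value, got {pair!r}")
        key, raw = pair.split("=", 1)
        key = key.strip()
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        cfg[key] = _coerce(key, types[key], raw)
    return RunConfig(**cfg)


def load_config(path=None, overrides=()) -> RunConfig:
    """Read a flat key=value file ('#' comments allowed), then apply overrides."""
    pairs = []
    if path is not None:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                pairs.append(line)
    return parse_overrides(list(pairs) + list(overrides))
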