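"""Pipeline configuration: one validated object shared by every stage."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .morphometry import AL_OFFSET_MM, DEFAULT_AL_BOUNDS, DEFAULT_REFERENCE_AL_MM


class ConfigError(ValueError):
    """Raised for out-of-range or malformed configuration."""


@dataclass
class PipelineConfig:
    reference_axial_length: float = DEFAULT_REFERENCE_AL_MM
    al_offset: float = AL_OFFSET_MM
    al_bounds: tuple[float, float] = DEFAULT_AL_BOUNDS
    nominal_pixel_size: float = 3000.0 / 304  # 3 mm scan over 304 A-scans
    box_sizes: list[int] | None = None  # None -> power-of-two ladder
    fd_substrate: str = "skeleton"  # or "binary"
    min_branch_length: float = 3.0
    prune_px: int = 0
    connectivity: int = 8
    entry_alpha: float = 0.1
    mw_exact_max_n: int = 12
    mw_use_continuity: bool = False
    seed: int = 0
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.al_bounds
        if not (0 < lo < hi):
            raise ConfigError("al_bounds must satisfy 0 < lo < hi")
        if not (lo <= self.reference_axial_length <= hi):
            raise ConfigError("reference_axial_length outside al_bounds")
        if self.nominal_pixel_size <= 0:
            raise ConfigError("nominal_pixel_size must be > 0")
        if self.fd_substrate not in ("skeleton", "binary"):
            raise ConfigError("fd_substrate must be 'skeleton' or 'binary'")
        if self.connectivity != 8:
            raise ConfigError("only 8-connectivity is supported")
        if not (0 < self.entry_alpha <= 1):
            raise ConfigError("entry_alpha must lie in (0, 1]")
        if self.min_branch_length < 0 or self.prune_px < 0:
            raise ConfigError("lengths must be non-negative")
        if self.box_sizes is not None:
            if len(self.box_sizes) < 3 or any(s < 1 for s in self.box_sizes):
                raise ConfigError("box_sizes needs >= 3 positive entries")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["al_bounds"] = list(self.al_bounds)
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load YAML or JSON config; missing path means all defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in data.items() if k in known}
    extra = {k: v for k, v in data.items() if k not in known}
    if "al_bounds" in kwargs:
        kwargs["al_bounds"] = tuple(kwargs["al_bounds"])
    try:
        return PipelineConfig(**kwargs, extra=extra)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
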