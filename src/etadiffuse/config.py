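"""Run configuration: YAML file merged with command-line overrides."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Diffusion/annotation settings shared by the CLI subcommands."""

    alpha: float = 1.0
    laplacian: str = "combinatorial"
    use_negatives: bool = True
    tolerance: float = 1e-8
    level: int = 4
    holdout: str = "batch"

    def __post_init__(self) -> None:
        if self.laplacian not in ("combinatorial", "normalized"):
            raise ValueError(f"laplacian must be combinatorial|normalized, got {self.laplacian!r}")
        if self.level not in (3, 4):
            raise ValueError(f"level must be 3 or 4, got {self.level}")
        if self.holdout not in ("batch", "loo"):
            raise ValueError(f"holdout must be batch|loo, got {self.holdout!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Override values of ``None`` are ignored so CLI flags that were not
    given fall through to the file (or the defaults).
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
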