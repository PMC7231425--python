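"""Run configuration: documented defaults, YAML loading, strict keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_ALGORITHMS = ("feec", "eem", "ap")


@dataclass
class RunConfig:
    """Parameters of a clustering run / evaluation protocol.

    ``preference=None`` means the median-of-similarities rule; a float
    fixes the preference directly.  ``n_repeats`` repeats the random
    complete/incomplete split with seeds ``seed .. seed + n_repeats - 1``.
    """

    algorithm: str = "feec"
    preference: float | None = None
    damping: float = 0.5
    max_iter: int = 1000
    conv_window: int = 50
    max_sweeps: int = 200
    energy_mode: str = "euclidean"
    r2_combination: str = "per_cluster"
    seed: int = 0
    n_repeats: int = 10
    incomplete_fraction: float = 0.2
    k_missing: int = 1
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}")
        if self.energy_mode not in ("euclidean", "squared"):
            raise ValueError("energy_mode must be 'euclidean' or 'squared'")
        if self.r2_combination not in ("per_cluster", "global"):
            raise ValueError("r2_combination must be 'per_cluster' or 'global'")
        if not (0.0 <= self.damping < 1.0):
            raise ValueError("damping must lie in [0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        mapping = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        return asdict(self)
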