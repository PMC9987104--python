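"""Pipeline configuration: every tunable in one validated object.

Thresholds carry their defaults from the analysis design: the regulator
screen keeps |r| > 0.3 at p < 0.05, the target funnel demands
lengthening at p < 0.001, and differential expression uses BH-FDR 0.05
with |log2FC| > 1.  Unknown keys and out-of-range values are rejected
up front, before any computation runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .pas import DEFAULT_NONCANONICAL_PAS

__all__ = ["PipelineConfig"]


def _in_range(name: str, value: float, lo: float, hi: float, *, open_lo: bool = False) -> None:
    ok = (lo < value if open_lo else lo <= value) and value <= hi
    if not ok:
        raise ValueError(f"config key {name!r}={value} outside [{lo},{hi}]")


@dataclass
class PipelineConfig:
    seed: int = 0
    # PDUI estimation
    end_margin: int = 50
    min_mean_depth: float = 5.0
    # APA change calls
    alpha: float = 0.05
    min_abs_delta: float = 0.05
    event_threshold: float = 0.2
    # regulator screen
    clustering_k: int = 3
    linkage: str = "average"
    deg_fdr_threshold: float = 0.05
    deg_lfc_threshold: float = 1.0
    r_threshold: float = 0.3
    p_threshold: float = 0.05
    # PAS typing
    noncanonical_hexamers: tuple[str, ...] = DEFAULT_NONCANONICAL_PAS
    distal_window: int = 50
    # target funnel
    lengthening_p_cutoff: float = 0.001
    min_pas: int = 2
    # cohort simulation
    n_genes: int = 500
    n_samples: int = 60
    subgroup_sizes: tuple[int, int, int] = (20, 20, 20)
    subgroup_shift: float = 0.25
    regulator_effect: float = 0.6

    def __post_init__(self) -> None:
        if self.end_margin < 1:
            raise ValueError("config key 'end_margin' must be >= 1")
        if self.min_mean_depth < 0:
            raise ValueError("config key 'min_mean_depth' must be >= 0")
        _in_range("alpha", self.alpha, 0.0, 1.0, open_lo=True)
        _in_range("min_abs_delta", self.min_abs_delta, 0.0, 1.0)
        _in_range("event_threshold", self.event_threshold, 0.0, 1.0, open_lo=True)
        if self.clustering_k < 2:
            raise ValueError("config key 'clustering_k' must be >= 2")
        if self.linkage not in ("average", "complete", "single", "ward"):
            raise ValueError(f"config key 'linkage'={self.linkage!r} is not supported")
        _in_range("deg_fdr_threshold", self.deg_fdr_threshold, 0.0, 1.0, open_lo=True)
        if self.deg_lfc_threshold < 0:
            raise ValueError("config key 'deg_lfc_threshold' must be >= 0")
        _in_range("r_threshold", self.r_threshold, 0.0, 1.0)
        _in_range("p_threshold", self.p_threshold, 0.0, 1.0, open_lo=True)
        _in_range("lengthening_p_cutoff", self.lengthening_p_cutoff, 0.0, 1.0, open_lo=True)
        if any(len(h) != 6 for h in self.noncanonical_hexamers):
            raise ValueError("config key 'noncanonical_hexamers' must hold hexamers")
        if self.distal_window < 1:
            raise ValueError("config key 'distal_window' must be >= 1")
        if self.min_pas < 0:
            raise ValueError("config key 'min_pas' must be >= 0")
        if self.n_genes < 1 or self.n_samples < 3:
            raise ValueError("config keys 'n_genes'/'n_samples' too small")
        if len(self.subgroup_sizes) != 3 or sum(self.subgroup_sizes) != self.n_samples:
            raise ValueError("config key 'subgroup_sizes' must be 3 counts summing to n_samples")
        _in_range("subgroup_shift", self.subgroup_shift, 0.0, 1.0)
        _in_range("regulator_effect", self.regulator_effect, 0.0, 1.0)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        data = dict(data)
        for key in ("subgroup_sizes", "noncanonical_hexamers"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["subgroup_sizes"] = list(d["subgroup_sizes"])
        d["noncanonical_hexamers"] = list(d["noncanonical_hexamers"])
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
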