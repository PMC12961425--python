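"""Run configuration: every tunable threshold with its protocol default.

The configuration round-trips through plain YAML so a run is fully
described by one text file; flat keys map 1:1 onto the threshold
dataclasses of the library modules.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .clustering import ClusterParams
from .curation import CurationThresholds
from .hitio import DEFAULT_GAP_MAX_NT, HitThresholds

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    hit: HitThresholds = field(default_factory=HitThresholds)
    curation: CurationThresholds = field(default_factory=CurationThresholds)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    release: str = "1.1"
    gap_max_nt: int = DEFAULT_GAP_MAX_NT
    host_gene_mode: str = "union"  # union | per_subject
    comparison_mode: str = "both"  # position | width | both
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("hit", HitThresholds), ("curation", CurationThresholds), ("cluster", ClusterParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the effective configuration."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
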