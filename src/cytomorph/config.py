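"""Run configuration with a stable content hash.

All stages of a run share one :class:`RunConfig`; its hash goes into the
run manifest so it is checkable that identical settings were applied to
every slide.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationParams


@dataclass
class RunConfig:
    """Tunables of the whole pipeline with their run defaults."""

    tile_size: int = 256
    stride: int = 256
    tiles_per_wsi: int = 250
    wsis_per_cat: int = 2
    tissue_downsample: int = 16
    tissue_fraction_threshold: float = 0.05
    contrast_margin: float = 15.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    bootstrap_reps: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """SHA-256 digest of the canonical JSON serialisation."""
        payload = json.dumps(self.to_dict(), sort_keys=True,
                             separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        seg = d.pop("segmentation", None)
        cfg = cls(**d)
        if seg is not None:
            cfg = dataclasses.replace(cfg,
                                      segmentation=SegmentationParams(**seg))
        return cfg
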