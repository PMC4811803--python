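"""Run configuration: acquisition geometry and analysis parameters."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class RunConfig:
    """Measurement parameters for a tracked movie.

    Defaults follow the standard acquisition of a fly notum time-lapse:
    0.32 um pixels, one frame every 5 min, 128-px coarse-graining boxes
    with 50% overlap, 2 h sliding averages, and a 5% relative tolerance
    on the deformation-rate balance check.
    """

    pixel_size_um: float = 0.32
    frame_interval_min: float = 5.0
    box_size_px: float = 128.0
    box_overlap: float = 0.5
    window_h: float = 2.0
    balance_tolerance: float = 0.05
    bulk_mode: str = "auto"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.box_overlap < 1:
            raise ValueError("box overlap must be in [0, 1)")
        if self.window_h * 60.0 < self.frame_interval_min:
            raise ValueError("averaging window shorter than the frame interval")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)
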