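"""Run configuration shared by the CLI commands: radius ranges in µm or px,
calibration, detector knobs and the master seed.  Serialises losslessly to
YAML/JSON."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hough import RadiusRange
from .pipeline import PipelineConfig
from .synthetic import DEFAULT_UM_PER_PX, OOCYTE_RANGE_UM, POLAR_BODY_RANGE_UM


@dataclass
class RunConfig:
    """User-facing configuration for detection and benchmarking.

    Each radius range uses exactly one unit system; µm ranges require a
    µm-per-pixel calibration to convert per image.
    """

    oocyte_range_um: tuple[float, float] | None = OOCYTE_RANGE_UM
    oocyte_range_px: tuple[float, float] | None = None
    pb_range_um: tuple[float, float] | None = POLAR_BODY_RANGE_UM
    pb_range_px: tuple[float, float] | None = None
    um_per_px: float | None = DEFAULT_UM_PER_PX
    mask_size: int = 5
    keep_fraction: float = 0.10
    min_confidence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for um, px, name in (
            (self.oocyte_range_um, self.oocyte_range_px, "oocyte"),
            (self.pb_range_um, self.pb_range_px, "polar body"),
        ):
            if (um is None) == (px is None):
                raise ValueError(f"{name} radius range needs exactly one unit system")
            if um is not None and self.um_per_px is None:
                raise ValueError(f"{name} range in µm requires um_per_px")
        if self.mask_size not in (3, 5):
            raise ValueError("mask_size must be 3 or 5")

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            mask_size=self.mask_size,
            keep_fraction=self.keep_fraction,
            min_confidence=self.min_confidence,
        )

    def radius_ranges(self, um_per_px: float | None = None) -> tuple[RadiusRange, RadiusRange]:
        """Radius ranges in pixels at the given (or configured) scale."""
        s = um_per_px if um_per_px is not None else self.um_per_px

        def convert(um, px):
            if px is not None:
                return RadiusRange(px[0], px[1])
            return RadiusRange(um[0] / s, um[1] / s)

        return (
            convert(self.oocyte_range_um, self.oocyte_range_px),
            convert(self.pb_range_um, self.pb_range_px),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("oocyte_range_um", "oocyte_range_px", "pb_range_um", "pb_range_px"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("oocyte_range_um", "oocyte_range_px", "pb_range_um", "pb_range_px"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)
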