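"""Run configuration: every preprocessing/QC tunable in one place.

Defaults are the study's stated values: 150 ms interpolation gap limit,
100 ms pupil smoothing window, 11 deg AOIs, 1.5-9 mm pupil validity range,
+-3 SD trial-level outlier recoding, 200 ms baseline window, 2 s response
window, 40%/25% gaze-occupancy thresholds, 0.2-1.0 s latency validity
bounds, 70% participant inclusion threshold, and m = 100 imputations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .schedule import POSITIONS


@dataclass
class RunConfig:
    # interpolation / smoothing
    max_gap_ms: float = 150.0
    smooth_ms: float = 100.0
    # geometry (visual degrees)
    aoi_side_deg: float = 11.0
    central_side_deg: float = 6.0
    screen_halfsize_deg: tuple[float, float] = (21.5, 12.5)
    layout: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(POSITIONS))
    # pupil validity and windows
    pupil_range_mm: tuple[float, float] = (1.5, 9.0)
    sd_k: float = 3.0
    baseline_ms: float = 200.0
    response_s: float = 2.0
    # gaze / QC thresholds
    min_dwell_ms: float = 100.0
    center_frac: float = 0.40
    c3_frac: float = 0.25
    c3_mode: str = "any"            # 'any' | 'all' | 'proportion'
    latency_bounds: tuple[float, float] = (0.2, 1.0)
    include_threshold: float = 0.70
    # analysis
    m_imputations: int = 100
    standardize: str = "global"     # 'global' | 'per_infant'
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["screen_halfsize_deg"] = list(d["screen_halfsize_deg"])
        d["pupil_range_mm"] = list(d["pupil_range_mm"])
        d["latency_bounds"] = list(d["latency_bounds"])
        d["layout"] = {k: list(v) for k, v in d["layout"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("screen_halfsize_deg", "pupil_range_mm", "latency_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        if "layout" in d:
            d["layout"] = {k: tuple(v) for k, v in d["layout"].items()}
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
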