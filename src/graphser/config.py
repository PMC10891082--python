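"""Run configuration and per-corpus presets.

All window/overlap values are in samples.  The presets bundle the
hyper-parameters reported as best per corpus (structural window/overlap on
the segment-mean series, statistical window/overlap on the raw signal, and
the random-forest size used for that corpus).  Explicit keys always override
preset values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Flat bag of every tunable the pipeline exposes."""

    # structural branch
    detector: str = "canny"
    threshold: float = 0.5          # sobel/prewitt gradient threshold
    canny_sigma: float = 1.0        # samples
    canny_low_pct: float = 70.0     # hysteresis percentiles of |gradient|
    canny_high_pct: float = 90.0
    min_segment_samples: int = 2
    struct_window: int = 50         # sliding-SD window on the mean series
    struct_overlap: int = 25
    pooling: str = "sd"             # "rms" selectable, off by default
    # statistical branch
    stat_window: int = 8000
    stat_overlap: int = 6000
    # evaluation
    n_trees: int = 300
    seed: int = 0
    # optional resampling before feature extraction (None = keep native rate)
    target_rate_hz: int | None = None

    def __post_init__(self) -> None:
        if self.struct_overlap >= self.struct_window or self.struct_overlap < 0:
            raise ParameterError("need 0 <= struct_overlap < struct_window")
        if self.stat_overlap >= self.stat_window or self.stat_overlap < 0:
            raise ParameterError("need 0 <= stat_overlap < stat_window")
        if self.n_trees < 1:
            raise ParameterError("n_trees must be positive")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: best-performing hyper-parameters per evaluated corpus (values in samples)
PRESETS: dict[str, dict] = {
    "emodb": dict(stat_window=10000, stat_overlap=2000, struct_window=200, struct_overlap=50,
                  n_trees=500, target_rate_hz=48000),
    "demos": dict(stat_window=8000, stat_overlap=6000, struct_window=100, struct_overlap=50,
                  n_trees=500),
    "aesdd": dict(stat_window=8000, stat_overlap=6000, struct_window=200, struct_overlap=100,
                  n_trees=300),
}

# JSON config files use dotted section keys; map them onto the flat dataclass
_KEY_MAP = {
    "structural.detector": "detector",
    "structural.threshold": "threshold",
    "structural.canny_sigma": "canny_sigma",
    "structural.canny_low_pct": "canny_low_pct",
    "structural.canny_high_pct": "canny_high_pct",
    "structural.min_segment_samples": "min_segment_samples",
    "structural.window": "struct_window",
    "structural.overlap": "struct_overlap",
    "structural.pooling": "pooling",
    "statistical.window": "stat_window",
    "statistical.overlap": "stat_overlap",
}


def _flatten(obj: dict, prefix: str = "") -> dict:
    out = {}
    for key, value in obj.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, f"{dotted}."))
        else:
            out[_KEY_MAP.get(dotted, dotted)] = value
    return out


def load_config(path=None, preset: str | None = None, **overrides) -> PipelineConfig:
    """Build a config with precedence: overrides > JSON file > preset > defaults."""
    values: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ParameterError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
        values.update(PRESETS[preset])
    if path is not None:
        with open(path) as handle:
            values.update(_flatten(json.load(handle)))
    values.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - fields
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)
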