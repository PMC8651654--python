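"""Run configuration: every pinned constant of the pipeline in one record.

The schema is strict — unknown keys are rejected — and round-trips
losslessly through YAML/JSON. Key names carry units (``window_s``,
``cutoff_um``) and every numeric default is the value used throughout the
analysis chain, so any number in an output table is traceable to a recorded
constant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input/output
    out_dir: str = "results/run"
    traces_path: str | None = None  # pre-extracted traces (CSV/HDF5); None = simulate
    whisk_path: str | None = None
    stack_path: str | None = None
    # simulation (used when traces_path is None)
    cohort: str = "app"  # 'wt' or 'app' preset
    n_neurons: int = 50
    n_sessions: int = 3
    frames_per_session: int = 5000
    frame_rate_hz: float = 10.0
    seed: int = 0
    # trace conditioning
    neuropil_factor: float = 0.7
    lowpass_cutoff_hz: float = 5.0
    detrend_window_s: float = 50.0
    detrend_pct: float = 8.0
    f0_short_window_s: float = 1.0
    noise_band_pct: float = 60.0
    # transient detection
    detect_smooth_frames: int = 5
    detect_k_sd: float = 3.0
    detect_duration_frames: int = 10
    detect_min_distance_frames: int = 15
    # binarized synchrony
    binarize_smooth_frames: int = 20
    binarize_k_sd: float = 2.0
    n_shuffles: int = 100
    distance_bin_edges_um: list = field(
        default_factory=lambda: [0.0, 50.0, 100.0, 150.0, 200.0]
    )
    # behavior
    whisk_min_duration_s: float = 0.33
    whisk_window_min_s: float = 1.0
    whisk_window_max_s: float = 2.0
    # plaque proximity
    proximity_cutoff_um: float = 40.0
    # aggregation level for reported statistics
    aggregation: str = "pooled"  # 'pooled' or 'fov'

    def __post_init__(self) -> None:
        if self.aggregation not in ("pooled", "fov"):
            raise ValueError("aggregation must be 'pooled' or 'fov'")
        if self.cohort not in ("wt", "app"):
            raise ValueError("cohort preset must be 'wt' or 'app'")

    # ---- round-tripping -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            return cls.from_yaml(path)
        return cls.from_dict(json.loads(path.read_text()))
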