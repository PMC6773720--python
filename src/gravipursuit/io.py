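"""Delimited-text IO, run configuration, and logging setup.

All tables are comma-separated UTF-8 with '.' decimals and a header
row; missing values are empty fields.  Gaze tables use the tracker
export schema (trial_id, t, x_surf, y_surf, confidence); an optional
column-rename mapping in the config adapts externally produced tables
with different column names to that schema.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import (ACC_THRESHOLD, ACCEL_LAG, CONFIDENCE_MIN, MERGE_GAP,
                       MIN_SACCADE_SAMPLES, SMOOTH_SIGMA, SURF_X_BOUNDS,
                       SURF_Y_BOUNDS, VEL_RATIO, VELOCITY_LAG, GazeTrace,
                       Geometry)
from .synthetic import SYSTEM_DELAY
from .timing import OUTLIER_THRESHOLD

logger = logging.getLogger("gravipursuit")

GAZE_COLUMNS = ("trial_id", "t", "x_surf", "y_surf", "confidence")


class SchemaError(ValueError):
    """A required column is absent."""


@dataclass
class RunConfig:
    """Seeds, geometry and pipeline constants for one analysis run.

    Every constant defaults to the analysis value (confidence cutoff
    0.9, display bounds x in [0, 1] / y in [-0.3, 1], velocity lag 9,
    acceleration lag 5, 300 m/s^2 and 1.5x saccade thresholds, 0.5 s
    timing outlier cutoff, 0.049259 s system delay) and can be
    overridden from a YAML file.
    """

    design_seed: int = 1
    cohort_seed: int = 2
    analysis_seed: int = 3
    screen_width: float = 1.84
    screen_height: float = 2.44
    view_distance: float = 2.0
    stimulus_depth: float = 6.15
    confidence_min: float = CONFIDENCE_MIN
    x_bounds: tuple[float, float] = SURF_X_BOUNDS
    y_bounds: tuple[float, float] = SURF_Y_BOUNDS
    smooth_sigma: float = SMOOTH_SIGMA
    velocity_lag: int = VELOCITY_LAG
    accel_lag: int = ACCEL_LAG
    acc_threshold: float = ACC_THRESHOLD
    vel_ratio: float = VEL_RATIO
    merge_gap: int = MERGE_GAP
    min_saccade_samples: int = MIN_SACCADE_SAMPLES
    outlier_threshold: float = OUTLIER_THRESHOLD
    system_delay: float = SYSTEM_DELAY
    column_map: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.screen_width, self.screen_height,
                        self.view_distance, self.stimulus_depth)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        kw = {k: v for k, v in raw.items() if k in known}
        for key in ("x_bounds", "y_bounds"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["x_bounds"] = list(d["x_bounds"])
        d["y_bounds"] = list(d["y_bounds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def setup_logging(verbosity: str = "INFO") -> None:
    """Log to stderr with levels; idempotent."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, verbosity.upper(), logging.INFO))


def read_gaze_table(path, column_map: dict | None = None) -> list[GazeTrace]:
    """Read a gaze-sample table into per-trial traces.

    Unknown columns warn; missing required columns raise naming the
    column.  Empty fields become NaN and are counted downstream by the
    missing-data filter stage.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"gaze table {path} lacks required column(s): "
                          f"{', '.join(missing)}")
    extra = [c for c in df.columns if c not in GAZE_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown gaze columns: {extra}")
    traces = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        traces.append(GazeTrace(str(trial_id),
                                g["t"].to_numpy(dtype=float),
                                g["x_surf"].to_numpy(dtype=float),
                                g["y_surf"].to_numpy(dtype=float),
                                g["confidence"].to_numpy(dtype=float)))
    return traces


def write_gaze_table(traces: list[GazeTrace], path) -> None:
    frames = [pd.DataFrame({"trial_id": tr.trial_id, "t": tr.t,
                            "x_surf": tr.x_surf, "y_surf": tr.y_surf,
                            "confidence": tr.confidence})
              for tr in traces]
    _atomic_write(pd.concat(frames, ignore_index=True), path)


def _atomic_write(df: pd.DataFrame, path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    tmp.replace(path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any tidy table atomically as CSV."""
    _atomic_write(df, path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
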