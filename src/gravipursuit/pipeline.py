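"""Gaze preprocessing: filtering, scene mapping, kinematics, saccades, gain.

Raw input is the surface-mapped export of a 200 Hz head-mounted eye
tracker: per-sample (t, x_surf, y_surf, confidence) with surface
coordinates normalised to the display.  The pipeline

1. drops low-confidence samples (< 0.9), then samples outside the
   display (x outside [0, 1], y outside [-0.3, 1]), then samples with
   missing data — each exclusion percentage is of the frames remaining
   after the previous stage;
2. maps surface coordinates to metric positions on the stimulus plane
   (screen-plane metres, ray-scaled from the viewpoint by the
   depth ratio);
3. smooths positions with a Gaussian kernel, differentiates with lagged
   differences (tangential speed, lag 9; its derivative, lag 5) using
   the recorded timestamps so dropped frames do not corrupt rates;
4. marks saccades where the lagged acceleration exceeds 300 m/s^2 or
   eye speed exceeds 1.5x the instantaneous target speed;
5. averages eye/target speed ratio over the non-saccadic samples
   between the first catch-up saccade's offset and occlusion onset —
   the per-trial pursuit gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

TRACKER_HZ = 200.0

# display-exclusion bounds in surface coordinates
SURF_X_BOUNDS = (0.0, 1.0)
SURF_Y_BOUNDS = (-0.3, 1.0)
CONFIDENCE_MIN = 0.9

VELOCITY_LAG = 9
ACCEL_LAG = 5
ACC_THRESHOLD = 300.0   # m/s^2 at the stimulus plane
VEL_RATIO = 1.5         # eye speed vs target speed
MERGE_GAP = 2           # samples between saccade segments to merge
MIN_SACCADE_SAMPLES = 2
SMOOTH_SIGMA = 3.0      # samples (15 ms at 200 Hz)


class PipelineError(ValueError):
    """Invalid pipeline input."""


@dataclass(frozen=True)
class Geometry:
    """Scene geometry: back-projection screen seen from 2 m, stimulus at 6.15 m."""

    screen_width: float = 1.84   # m
    screen_height: float = 2.44  # m
    view_distance: float = 2.0   # m
    stimulus_depth: float = 6.15  # m

    @property
    def depth_scale(self) -> float:
        return self.stimulus_depth / self.view_distance


@dataclass
class GazeTrace:
    """Raw per-trial gaze samples in surface coordinates."""

    trial_id: str
    t: np.ndarray
    x_surf: np.ndarray
    y_surf: np.ndarray
    confidence: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FilterReport:
    """Per-stage exclusion counts (stage-wise denominators)."""

    n_total: int
    n_low_confidence: int
    n_out_of_bounds: int
    n_missing: int

    @property
    def n_kept(self) -> int:
        return (self.n_total - self.n_low_confidence - self.n_out_of_bounds
                - self.n_missing)

    @property
    def frac_low_confidence(self) -> float:
        return self.n_low_confidence / self.n_total if self.n_total else np.nan

    @property
    def frac_out_of_bounds(self) -> float:
        rem = self.n_total - self.n_low_confidence
        return self.n_out_of_bounds / rem if rem else np.nan

    @property
    def frac_missing(self) -> float:
        rem = self.n_total - self.n_low_confidence - self.n_out_of_bounds
        return self.n_missing / rem if rem else np.nan


@dataclass
class KinematicSeries:
    """Scene-mapped, smoothed gaze kinematics for one trial."""

    t: np.ndarray
    pos: np.ndarray          # (n, 2) scene metres at the stimulus plane
    pos_smooth: np.ndarray
    v_tan: np.ndarray        # m/s, NaN where undefined
    acc: np.ndarray          # m/s^2, NaN where undefined
    saccade_mask: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SaccadeSegment:
    """One detected saccade: onset/offset times and the landing position."""

    onset_idx: int
    offset_idx: int
    onset_t: float
    offset_t: float
    landing_pos: tuple[float, float]


@dataclass(frozen=True)
class PursuitSummary:
    """Per-trial pursuit gain and bookkeeping."""

    gain: float
    n_eligible: int
    first_catchup_offset_t: float
    n_saccades: int
    valid: bool = True


# ---------------------------------------------------------------------------
# stage 1: filtering

def filter_trace(trace: GazeTrace,
                 confidence_min: float = CONFIDENCE_MIN,
                 x_bounds: tuple[float, float] = SURF_X_BOUNDS,
                 y_bounds: tuple[float, float] = SURF_Y_BOUNDS,
                 ) -> tuple[GazeTrace, FilterReport]:
    """Apply the staged exclusions; NaN comparisons never pass a bound check,
    so samples with missing coordinates fall through to the missing stage."""
    n_total = len(trace)
    conf_bad = trace.confidence < confidence_min
    keep1 = ~conf_bad
    with np.errstate(invalid="ignore"):
        oob = ((trace.x_surf < x_bounds[0]) | (trace.x_surf > x_bounds[1])
               | (trace.y_surf < y_bounds[0]) | (trace.y_surf > y_bounds[1]))
    oob = oob & keep1
    keep2 = keep1 & ~oob
    missing = (np.isnan(trace.t) | np.isnan(trace.x_surf)
               | np.isnan(trace.y_surf) | np.isnan(trace.confidence))
    missing = missing & keep2
    keep = keep2 & ~missing
    report = FilterReport(n_total=n_total,
                          n_low_confidence=int(conf_bad.sum()),
                          n_out_of_bounds=int(oob.sum()),
                          n_missing=int(missing.sum()))
    filtered = GazeTrace(trace.trial_id, trace.t[keep], trace.x_surf[keep],
                         trace.y_surf[keep], trace.confidence[keep])
    return filtered, report


# ---------------------------------------------------------------------------
# stage 2: scene mapping

def map_to_scene(x_surf, y_surf, geometry: Geometry = Geometry()):
    """Surface coordinates -> metres at the stimulus plane.

    Surface (0..1, 0..1) spans the screen; coordinates are centred on
    the screen, converted to screen-plane metres and ray-scaled about
    the viewpoint by depth/viewing-distance (similar triangles)."""
    s = geometry.depth_scale
    x = (np.asarray(x_surf, dtype=float) - 0.5) * geometry.screen_width * s
    y = (np.asarray(y_surf, dtype=float) - 0.5) * geometry.screen_height * s
    return x, y


def scene_to_surface(x, y, geometry: Geometry = Geometry()):
    """Inverse of :func:`map_to_scene` (exact)."""
    s = geometry.depth_scale
    x_surf = np.asarray(x, dtype=float) / (geometry.screen_width * s) + 0.5
    y_surf = np.asarray(y, dtype=float) / (geometry.screen_height * s) + 0.5
    return x_surf, y_surf


# ---------------------------------------------------------------------------
# stage 3: smoothing and lagged derivatives

def smooth(pos: np.ndarray, sigma_samples: float = SMOOTH_SIGMA) -> np.ndarray:
    """Gaussian smoothing per coordinate, reflecting boundaries."""
    if sigma_samples <= 0:
        raise PipelineError("sigma must be positive")
    return gaussian_filter1d(np.asarray(pos, dtype=float), sigma_samples,
                             axis=0, mode="reflect")


def _lagged_rate(t: np.ndarray, values: np.ndarray, lag: int,
                 max_gap: float) -> np.ndarray:
    """Lagged difference quotient assigned to the window centre.

    ``values`` is (n,) for a scalar series or (n, 2) for positions, in
    which case the Euclidean step length is used (tangential speed).
    Windows spanning a time gap larger than ``max_gap`` are masked NaN.
    """
    n = len(t)
    out = np.full(n, np.nan)
    if n <= lag:
        return out
    dt = t[lag:] - t[:-lag]
    if values.ndim == 2:
        step = np.linalg.norm(values[lag:] - values[:-lag], axis=1)
    else:
        step = values[lag:] - values[:-lag]
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = step / dt
    rate[dt > max_gap] = np.nan
    rate[dt <= 0] = np.nan
    centre = np.arange(lag, n) - lag // 2
    out[centre] = rate
    return out


def tangential_velocity(t: np.ndarray, pos_smooth: np.ndarray,
                        lag: int = VELOCITY_LAG,
                        sample_interval: float = 1.0 / TRACKER_HZ) -> np.ndarray:
    """Tangential eye speed from lagged positional differences (m/s, >= 0)."""
    if len(t) <= lag:
        return np.full(len(t), np.nan)
    return _lagged_rate(t, pos_smooth, lag, max_gap=3 * lag * sample_interval)


def acceleration(t: np.ndarray, v_tan: np.ndarray, lag: int = ACCEL_LAG,
                 sample_interval: float = 1.0 / TRACKER_HZ) -> np.ndarray:
    """Lagged time-derivative of the tangential speed (m/s^2, signed)."""
    return _lagged_rate(t, v_tan, lag, max_gap=3 * lag * sample_interval)


# ---------------------------------------------------------------------------
# stage 4: saccade classification

def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is inclusive."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, stops))


def classify_saccades(series: KinematicSeries, target_speed,
                      acc_threshold: float = ACC_THRESHOLD,
                      vel_ratio: float = VEL_RATIO,
                      merge_gap: int = MERGE_GAP,
                      min_dur: int = MIN_SACCADE_SAMPLES,
                      ) -> tuple[list[SaccadeSegment], np.ndarray]:
    """Threshold classifier: acceleration OR velocity-ratio criterion.

    ``target_speed`` maps times to the target's instantaneous
    tangential speed.  Segments closer than ``merge_gap`` samples merge;
    segments shorter than ``min_dur`` samples are dropped.
    """
    v_target = np.asarray(target_speed(series.t), dtype=float)
    with np.errstate(invalid="ignore"):
        raw = (series.acc > acc_threshold) | (series.v_tan > vel_ratio * v_target)
    raw = np.where(np.isnan(series.v_tan), False, raw)

    runs = _runs(raw)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    segments = []
    mask = np.zeros(len(series.t), dtype=bool)
    for start, stop in merged:
        if stop - start + 1 < min_dur:
            continue
        mask[start:stop + 1] = True
        segments.append(SaccadeSegment(
            onset_idx=int(start), offset_idx=int(stop),
            onset_t=float(series.t[start]), offset_t=float(series.t[stop]),
            landing_pos=(float(series.pos_smooth[stop, 0]),
                         float(series.pos_smooth[stop, 1]))))
    return segments, mask


# ---------------------------------------------------------------------------
# stage 5: pursuit gain

#: samples excluded around each saccade when averaging the gain: the
#: lag-9 velocity window reaches lag//2 samples past a segment edge and
#: Gaussian smoothing spreads the saccadic step by ~sigma further, so
#: speed estimates within this margin still carry saccadic displacement
GAIN_MASK_MARGIN = VELOCITY_LAG // 2 + int(np.ceil(SMOOTH_SIGMA)) + 1


def _dilate(mask: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0 or not mask.any():
        return mask
    out = mask.copy()
    for shift in range(1, margin + 1):
        out[:-shift] |= mask[shift:]
        out[shift:] |= mask[:-shift]
    return out


def compute_gain(series: KinematicSeries, segments: list[SaccadeSegment],
                 t_occ: float, target_speed, motion_onset: float = 0.0,
                 fallback_start: float | None = None,
                 saccade_margin: int = GAIN_MASK_MARGIN) -> PursuitSummary:
    """Average eye/target speed ratio over the eligible pursuit window.

    The window opens at the offset of the first saccade after motion
    onset (the catch-up saccade) and closes at occlusion onset; samples
    inside saccades — widened by ``saccade_margin`` samples on each
    side, because lagged differentiation smears saccadic displacement
    into neighbouring speed estimates — or with undefined speed are
    excluded.
    """
    first = next((s for s in segments if s.onset_t >= motion_onset), None)
    if first is not None:
        start = first.offset_t
    elif fallback_start is not None:
        start = fallback_start
    else:
        return PursuitSummary(np.nan, 0, np.nan, len(segments), valid=False)

    v_target = np.asarray(target_speed(series.t), dtype=float)
    mask = series.saccade_mask
    if mask is None:
        mask = np.zeros(len(series.t), dtype=bool)
    mask = _dilate(mask, saccade_margin)
    with np.errstate(invalid="ignore", divide="ignore"):
        eligible = ((series.t > start) & (series.t < t_occ) & ~mask
                    & np.isfinite(series.v_tan) & (v_target > 0))
        ratio = series.v_tan[eligible] / v_target[eligible]
    n = int(eligible.sum())
    if n == 0:
        return PursuitSummary(np.nan, 0, start, len(segments), valid=False)
    return PursuitSummary(float(np.mean(ratio)), n, start, len(segments))


# ---------------------------------------------------------------------------
# full per-trial pipeline

@dataclass
class TrialResult:
    """Everything the per-trial pipeline produces."""

    trial_id: str
    report: FilterReport
    series: KinematicSeries | None
    segments: list[SaccadeSegment]
    summary: PursuitSummary


def process_trace(trace: GazeTrace, target_speed, t_occ: float,
                  geometry: Geometry = Geometry(),
                  sigma: float = SMOOTH_SIGMA,
                  velocity_lag: int = VELOCITY_LAG,
                  accel_lag: int = ACCEL_LAG,
                  acc_threshold: float = ACC_THRESHOLD,
                  vel_ratio: float = VEL_RATIO,
                  merge_gap: int = MERGE_GAP,
                  min_dur: int = MIN_SACCADE_SAMPLES,
                  fallback_start: float | None = None,
                  saccade_margin: int = GAIN_MASK_MARGIN) -> TrialResult:
    """Filter -> map -> smooth -> differentiate -> classify -> gain."""
    filtered, report = filter_trace(trace)
    if report.n_kept < velocity_lag + 1:
        return TrialResult(trace.trial_id, report, None, [],
                           PursuitSummary(np.nan, 0, np.nan, 0, valid=False))
    x, y = map_to_scene(filtered.x_surf, filtered.y_surf, geometry)
    pos = np.column_stack([x, y])
    pos_smooth = smooth(pos, sigma)
    v_tan = tangential_velocity(filtered.t, pos_smooth, velocity_lag)
    acc = acceleration(filtered.t, v_tan, accel_lag)
    series = KinematicSeries(t=filtered.t, pos=pos, pos_smooth=pos_smooth,
                             v_tan=v_tan, acc=acc)
    segments, mask = classify_saccades(series, target_speed, acc_threshold,
                                       vel_ratio, merge_gap, min_dur)
    series.saccade_mask = mask
    summary = compute_gain(series, segments, t_occ, target_speed,
                           fallback_start=fallback_start,
                           saccade_margin=saccade_margin)
    return TrialResult(trace.trial_id, report, series, segments, summary)
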