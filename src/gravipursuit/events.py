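"""Saccade- and lag-based exploratory metrics.

Derived per trial from the classified kinematic series:

* horizontal landing error of the first saccade after occlusion onset
  relative to where the target meets the table (negative = saccade
  landed to the left, an undershoot);
* gaze-target lag at a reference time (40 % of the return time for the
  inversion block, a fixed 0.4 s after motion onset for the graded
  gravity blocks);
* number of saccades overlapping a window;
* gaze-target error at the offset of the first catch-up saccade.

All metrics are missing-safe: when the defining event does not occur
the metric is NaN, never a fabricated zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import KinematicSeries, SaccadeSegment

#: reference rules for the gaze-target lag
RULE_FRACTION_40PCT = "fraction_40pct"
RULE_AFTER_0P4S = "after_0.4s"

LAG_REFERENCE_S = 0.4
LAG_REFERENCE_FRACTION = 0.4
_NEAREST_UNMASKED = 5  # samples searched around a masked reference


@dataclass(frozen=True)
class LagMetrics:
    """Gaze minus target position at the reference sample (m)."""

    dx: float
    dy: float
    reference_t: float
    reference_rule: str


def occlusion_saccade_error_x(series: KinematicSeries,
                              segments: list[SaccadeSegment],
                              t_occ: float, x_coincidence: float) -> float:
    """Landing x of the first post-occlusion saccade minus the
    coincidence x; NaN when no saccade starts after occlusion onset."""
    first = next((s for s in segments if s.onset_t > t_occ), None)
    if first is None:
        return np.nan
    return first.landing_pos[0] - x_coincidence


def _reference_time(rule: str, t_return: float) -> float:
    if rule == RULE_FRACTION_40PCT:
        return LAG_REFERENCE_FRACTION * t_return
    if rule == RULE_AFTER_0P4S:
        return LAG_REFERENCE_S
    raise ValueError(f"unknown lag reference rule {rule!r}")


def gaze_lag_at(series: KinematicSeries, target_pos, rule: str,
                t_return: float) -> LagMetrics:
    """Gaze-target offset at the rule's reference time.

    ``target_pos(t)`` returns the target (x, y).  If the reference
    sample is saccade-masked or undefined, the nearest clean sample
    within +-5 samples substitutes; otherwise the metric is missing.
    """
    t_ref = _reference_time(rule, t_return)
    if len(series.t) == 0 or t_ref < series.t[0] or t_ref > series.t[-1]:
        return LagMetrics(np.nan, np.nan, t_ref, rule)
    i = int(np.argmin(np.abs(series.t - t_ref)))
    mask = series.saccade_mask
    bad = (mask is not None and mask[i]) or not np.all(np.isfinite(series.pos_smooth[i]))
    if bad:
        for off in range(1, _NEAREST_UNMASKED + 1):
            for j in (i - off, i + off):
                if 0 <= j < len(series.t):
                    ok = (mask is None or not mask[j]) and \
                        np.all(np.isfinite(series.pos_smooth[j]))
                    if ok:
                        i = j
                        bad = False
                        break
            if not bad:
                break
        if bad:
            return LagMetrics(np.nan, np.nan, t_ref, rule)
    tx, ty = target_pos(series.t[i])
    return LagMetrics(float(series.pos_smooth[i, 0] - tx),
                      float(series.pos_smooth[i, 1] - ty),
                      float(series.t[i]), rule)


def count_saccades(segments: list[SaccadeSegment],
                   window: tuple[float, float]) -> int:
    """Number of saccade segments overlapping [window_start, window_end]."""
    lo, hi = window
    return sum(1 for s in segments if s.offset_t >= lo and s.onset_t <= hi)


def catchup_saccade_error(series: KinematicSeries,
                          segments: list[SaccadeSegment], target_pos,
                          motion_onset: float = 0.0) -> tuple[float, float]:
    """(gaze - target) at the first catch-up saccade's offset sample;
    (NaN, NaN) when no saccade follows motion onset."""
    first = next((s for s in segments if s.onset_t >= motion_onset), None)
    if first is None:
        return (np.nan, np.nan)
    tx, ty = target_pos(first.offset_t)
    return (first.landing_pos[0] - float(tx), first.landing_pos[1] - float(ty))
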