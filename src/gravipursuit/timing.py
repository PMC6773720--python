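"""Coincidence-timing errors and the earth-gravity extrapolation model.

The observed temporal error of a trial is the button-press time minus
the true coincidence time (negative = pressed too early); the display
system delay (0.049259 s by default) is subtracted to give the
corrected error, and trials with |raw error| >= 0.5 s are excluded as
outliers.

Two per-trial predictions are compared with the observed errors:

* ``predicted_error_1g`` — the drag-free earth-gravity extrapolation of
  the true stimulus state at occlusion onset, minus the true remaining
  flight time.  Low gravities make this negative (earth gravity expects
  a faster fall than the stimulus delivers), high gravities positive.
* ``predicted_error_central`` — a pure regression-to-the-mean observer
  who times every occlusion by the mean occluded duration of its block
  type.

``compare_models`` reports Pearson correlations between observed and
predicted errors (overall and per occlusion category) and cell medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import trajectory as traj
from .design import TrialCondition
from .synthetic import SYSTEM_DELAY

OUTLIER_THRESHOLD = 0.5  # s, on |raw error|


@dataclass(frozen=True)
class TimingResult:
    """Observed timing of one trial."""

    t_response: float
    t_coincidence: float
    raw_error: float
    corrected_error: float
    excluded: bool
    reason: str = ""


@dataclass(frozen=True)
class ModelPrediction:
    """Model-predicted temporal errors for one trial."""

    predicted_error_1g: float
    predicted_error_central: float


def temporal_error(t_response: float, params: traj.TrajectoryParams,
                   system_delay: float = SYSTEM_DELAY,
                   outlier_threshold: float = OUTLIER_THRESHOLD,
                   t_coincidence: float | None = None) -> TimingResult:
    """Raw and delay-corrected temporal error with the outlier flag.

    The outlier rule reads the 0.5 s cutoff as an absolute value: both
    very early and very late presses are discarded.
    """
    T = traj.return_time(params) if t_coincidence is None else t_coincidence
    if t_response is None or not np.isfinite(t_response):
        return TimingResult(np.nan, T, np.nan, np.nan, True, "missing response")
    raw = t_response - T
    excluded = abs(raw) >= outlier_threshold
    return TimingResult(t_response, T, raw, raw - system_delay, excluded,
                        "outlier" if excluded else "")


def predict_error_1g(params: traj.TrajectoryParams, t_occ: float) -> float:
    """Earth-gravity extrapolated remaining time minus the true one.

    The extrapolation ignores drag and uses 9.81 m/s^2 regardless of
    the gravity governing the stimulus; the state (vertical velocity
    and remaining distance) is the true stimulus state at occlusion.
    """
    ttc_hat = traj.predict_ttc_1g(traj.ttc_query_at(params, t_occ))
    return ttc_hat - (traj.return_time(params) - t_occ)


def predict_error_central(occluded_duration: float,
                          mean_occluded_duration: float) -> float:
    """Central-tendency predicted error: block-mean minus actual
    occluded duration."""
    return mean_occluded_duration - occluded_duration


def predictions_for(cond: TrialCondition,
                    mean_occluded_duration: float) -> ModelPrediction:
    params = traj.params_for(cond.gravity_mult, cond.v_xi, cond.v_yi)
    t_occ = traj.occlusion_onset(params, cond.occ_fraction)
    occluded = traj.return_time(params) - t_occ
    return ModelPrediction(
        predicted_error_1g=predict_error_1g(params, t_occ),
        predicted_error_central=predict_error_central(
            occluded, mean_occluded_duration))


def add_timing_columns(frame: pd.DataFrame,
                       system_delay: float = SYSTEM_DELAY,
                       outlier_threshold: float = OUTLIER_THRESHOLD,
                       ) -> pd.DataFrame:
    """Attach observed errors and both model predictions to a tidy
    cohort table (requires t_response, t_coincidence, t_occ,
    occluded_duration, block_type, gravity_mult, v_xi, v_yi columns)."""
    out = frame.copy()
    out["raw_error"] = out["t_response"] - out["t_coincidence"]
    out["corrected_error"] = out["raw_error"] - system_delay
    out["excluded"] = out["raw_error"].abs() >= outlier_threshold
    out.loc[out["raw_error"].isna(), "excluded"] = True

    pred_1g = np.empty(len(out))
    for key, idx in out.groupby(["gravity_mult", "v_xi", "v_yi",
                                 "occ_fraction"]).groups.items():
        gm, vx, vy, frac = key
        params = traj.params_for(gm, vx, vy)
        t_occ = traj.occlusion_onset(params, frac)
        pred_1g[out.index.get_indexer(idx)] = predict_error_1g(params, t_occ)
    out["predicted_1g"] = pred_1g
    mean_dur = out.groupby("block_type")["occluded_duration"].transform("mean")
    out["predicted_central"] = mean_dur - out["occluded_duration"]
    return out


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(sps.pearsonr(a[ok], b[ok]).statistic)


def compare_models(frame: pd.DataFrame,
                   predictors: tuple[str, ...] = ("predicted_1g",
                                                  "predicted_central"),
                   ) -> dict:
    """Observed-vs-predicted correlations and per-cell medians.

    Uses non-excluded trials.  Returns, per predictor, the overall
    Pearson r and the r per occlusion category, plus a table of median
    observed and predicted errors per gravity x occlusion cell, and the
    name of the predictor with the highest overall r.
    """
    data = frame.loc[~frame["excluded"]]
    obs = data["corrected_error"].to_numpy()
    result: dict = {"n": len(data), "correlations": {}}
    for pred in predictors:
        p = data[pred].to_numpy()
        by_occ = {occ: _safe_pearson(
            data.loc[data["occ_category"] == occ, "corrected_error"].to_numpy(),
            data.loc[data["occ_category"] == occ, pred].to_numpy())
            for occ in data["occ_category"].unique()}
        result["correlations"][pred] = {"overall": _safe_pearson(obs, p),
                                        "by_occlusion": by_occ}
    medians = (data.groupby(["gravity_mult", "occ_category"])
               [["corrected_error", *predictors]].median().reset_index())
    result["cell_medians"] = medians
    overall = {p: result["correlations"][p]["overall"] for p in predictors}
    finite = {p: r for p, r in overall.items() if np.isfinite(r)}
    result["best_predictor"] = max(finite, key=finite.get) if finite else None
    return result
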