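"""Synthetic gaze traces and coincidence responses.

Generates data with the statistical structure the analysis assumes, so
every downstream stage can be exercised and validated without recorded
eye movements:

* **Oculomotor model** — after a pursuit latency the eye makes a first
  catch-up saccade onto the target, then pursues with eye velocity equal
  to a per-trial gain times the target velocity.  Positional error
  accumulating under imperfect gain triggers further catch-up saccades
  (minimum-jerk position steps) whenever it exceeds a threshold.  After
  occlusion onset the pursuit gain decays exponentially and a single
  predictive saccade is launched toward the landing point an
  earth-gravity extrapolation of the last seen state implies.
* **Measurement model** — positional noise at the stimulus plane,
  confidence dropouts (a fraction of frames get confidence below the
  0.9 analysis threshold), sampling at the 200 Hz tracker rate, output
  mapped to display-surface coordinates (the tracker's export schema).
* **Timing model** — a button press at occlusion onset plus a mixture
  of the earth-gravity extrapolated time-to-contact and the cohort-mean
  occluded duration (central tendency), plus motor noise and the
  display system delay.
* **Cohort model** — per-subject random intercepts on gain, plus
  trial-to-trial gain noise six times larger (the within/between
  variability ratio the design assumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import trajectory as traj
from .design import TrialCondition, build_experiment
from .pipeline import Geometry, GazeTrace, scene_to_surface

TRACKER_DT = 1.0 / 200.0

#: default display system delay (s) added to every simulated response
SYSTEM_DELAY = 0.049259


@dataclass(frozen=True)
class OculomotorProfile:
    """Parameters of the synthetic pursuit/saccade behaviour.

    ``gain_true`` may be a scalar or a mapping gravity multiplier ->
    gain, letting cohorts embed gravity-dependent pursuit quality.
    Distances are metres at the stimulus plane.
    """

    gain_true: float | Mapping[float, float] = 0.9
    pursuit_latency: float = 0.15      # s before the first catch-up saccade
    catchup_threshold: float = 0.3     # m positional error triggering a saccade
    saccade_duration: float = 0.05     # s
    dropout_rate: float = 0.064        # P(confidence < 0.9)
    pos_noise_sd: float = 0.005        # m, per sample per coordinate
    subject_intercept_sd: float = 0.025  # gain units, between subjects
    trial_noise_sd: float = 0.15         # gain units, within subject (6x)
    occlusion_gain_tau: float = 0.3    # s, pursuit gain decay after occlusion
    occlusion_saccade_latency: float = 0.21  # s after occlusion onset
    predictive_saccade: bool = True
    catchup_landing_offset: tuple[float, float] = (0.0, 0.0)  # m, saccade error
    #: extra saccades forced at fixed times (s), for injection tests
    scheduled_saccades: tuple[float, ...] = ()

    def gain_for(self, gravity_mult: float) -> float:
        if isinstance(self.gain_true, Mapping):
            return float(self.gain_true[gravity_mult])
        return float(self.gain_true)


@dataclass(frozen=True)
class TimingBehavior:
    """Parameters of the synthetic coincidence-timing responses.

    ``lambda_central`` mixes the earth-gravity extrapolation (0) with a
    pure central-tendency strategy (1) that times every response by the
    mean occluded duration.
    """

    lambda_central: float = 0.0
    motor_noise_sd: float = 0.05   # s
    response_offset: float = 0.0   # s, constant bias
    system_delay: float = SYSTEM_DELAY

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_central <= 1.0:
            raise ValueError("lambda_central must be in [0, 1]")
        if self.system_delay < 0:
            raise ValueError("system_delay must be >= 0")


@dataclass
class TrialTruth:
    """Ground truth of one simulated trace, for recovery tests."""

    gain: float
    t_occ: float
    t_return: float
    saccades: list[tuple[float, float]] = field(default_factory=list)
    predicted_landing_x: float | None = None


def _min_jerk_profile(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def condition_params(cond: TrialCondition) -> traj.TrajectoryParams:
    return traj.params_for(cond.gravity_mult, cond.v_xi, cond.v_yi)


def simulate_trial_gaze(cond: TrialCondition, profile: OculomotorProfile,
                        rng_seed, gain_trial: float | None = None,
                        geometry: Geometry = Geometry(),
                        return_truth: bool = False):
    """Simulate one trial's gaze trace in tracker surface coordinates.

    ``gain_trial`` overrides the profile gain (used by the cohort
    generator to add subject and trial noise).  With ``return_truth``
    the injected saccade times and the per-trial gain come along for
    recovery tests.
    """
    rng = _as_rng(rng_seed)
    params = condition_params(cond)
    T = traj.return_time(params)
    t_occ = traj.occlusion_onset(params, cond.occ_fraction)
    gain = profile.gain_for(cond.gravity_mult) if gain_trial is None else gain_trial

    n_sacc = max(int(round(profile.saccade_duration / TRACKER_DT)), 1)
    t_pred = t_occ + profile.occlusion_saccade_latency
    t_end = max(T, t_pred + profile.saccade_duration) + 0.05
    t = np.arange(0.0, t_end, TRACKER_DT)
    n = len(t)
    st = traj.position(params, t)
    tpos = np.column_stack([st.x, st.y])
    tvel = np.column_stack([st.vx, st.vy])

    # pursuit gain schedule: constant while visible, decaying after occlusion
    gain_t = np.full(n, gain)
    occluded = t >= t_occ
    gain_t[occluded] = gain * np.exp(-(t[occluded] - t_occ)
                                     / profile.occlusion_gain_tau)
    # per-step trapezoidal position increments of pure pursuit
    v_scaled = gain_t[:, None] * tvel
    dstep = 0.5 * (v_scaled[1:] + v_scaled[:-1]) * np.diff(t)[:, None]

    truth = TrialTruth(gain=gain, t_occ=t_occ, t_return=T)
    eye = np.empty((n, 2))

    # fixation at the launch point until pursuit latency
    i_lat = int(np.searchsorted(t, profile.pursuit_latency))
    i_lat = min(max(i_lat, 0), n - 1)
    eye[:i_lat + 1] = tpos[0]

    def insert_saccade(j0: int, landing: np.ndarray) -> int:
        j1 = min(j0 + n_sacc, n - 1)
        u = (t[j0:j1 + 1] - t[j0]) / (t[j1] - t[j0]) if j1 > j0 else np.array([1.0])
        s = _min_jerk_profile(u)
        eye[j0:j1 + 1] = eye[j0] + s[:, None] * (landing - eye[j0])
        truth.saccades.append((float(t[j0]), float(t[j1])))
        return j1

    offset = np.asarray(profile.catchup_landing_offset)
    # first catch-up saccade onto the target
    j_land = min(i_lat + n_sacc, n - 1)
    anchor = insert_saccade(i_lat, tpos[j_land] + offset)

    # predictive saccade target: earth-gravity extrapolation of the state
    # at occlusion onset, landing at the coincidence height
    pred_landing = None
    if profile.predictive_saccade:
        st_occ = traj.position(params, t_occ)
        ttc_hat = traj.predict_ttc_1g(traj.ttc_query_at(params, t_occ))
        x_hat = st_occ.x + st_occ.vx * ttc_hat
        pred_landing = np.array([x_hat, params.start_y])
        truth.predicted_landing_x = float(x_hat)
    pred_done = pred_landing is None

    thr = profile.catchup_threshold
    scheduled = sorted(profile.scheduled_saccades)
    while anchor < n - 1:
        seg = np.arange(anchor, n)
        path = eye[anchor] + np.concatenate(
            [[np.zeros(2)], np.cumsum(dstep[anchor:], axis=0)])
        err = np.linalg.norm(tpos[seg] - path, axis=1)
        trigger = np.flatnonzero((err > thr) & (t[seg] < t_occ) & (seg > anchor))
        j_err = seg[trigger[0]] if trigger.size else n
        j_pred = n
        if not pred_done:
            j_pred = int(np.searchsorted(t, t_pred))
        j_sched = n
        if scheduled:
            j_sched = max(int(np.searchsorted(t, scheduled[0])), anchor + 1)
        j0 = min(j_err, j_pred, j_sched)
        if j0 >= n - 1:
            eye[anchor:] = path[:n - anchor]
            break
        eye[anchor:j0 + 1] = path[:j0 - anchor + 1]
        if j0 == j_pred and not pred_done:
            anchor = insert_saccade(j0, pred_landing)
            pred_done = True
        else:
            if j0 == j_sched and scheduled:
                scheduled.pop(0)
            j1 = min(j0 + n_sacc, n - 1)
            anchor = insert_saccade(j0, tpos[j1] + offset)

    if profile.pos_noise_sd > 0:
        eye = eye + rng.normal(0.0, profile.pos_noise_sd, size=eye.shape)

    x_surf, y_surf = scene_to_surface(eye[:, 0], eye[:, 1], geometry)
    drop = rng.random(n) < profile.dropout_rate
    confidence = np.where(drop, rng.uniform(0.0, 0.9, n), rng.uniform(0.9, 1.0, n))

    trial_id = f"{cond.block_type}_{cond.trial_index}"
    trace = GazeTrace(trial_id, t, x_surf, y_surf, confidence)
    if return_truth:
        return trace, truth
    return trace


def simulate_response(cond: TrialCondition, behavior: TimingBehavior,
                      rng_seed, central_duration: float | None = None) -> float:
    """Simulated button-press time (absolute, from motion onset).

    The occluded interval is timed by mixing the earth-gravity
    extrapolated time-to-contact with the cohort-mean occluded duration
    according to ``lambda_central``; motor noise and the display system
    delay are added on top.
    """
    rng = _as_rng(rng_seed)
    params = condition_params(cond)
    t_occ = traj.occlusion_onset(params, cond.occ_fraction)
    lam = behavior.lambda_central
    if lam > 0 and central_duration is None:
        raise ValueError("central_duration required when lambda_central > 0")
    ttc_hat = traj.predict_ttc_1g(traj.ttc_query_at(params, t_occ))
    interval = (1.0 - lam) * ttc_hat + lam * (central_duration or 0.0)
    noise = rng.normal(behavior.response_offset, behavior.motor_noise_sd) \
        if behavior.motor_noise_sd > 0 else behavior.response_offset
    return t_occ + interval + noise + behavior.system_delay


def simulate_cohort(n_subjects: int,
                    profile: OculomotorProfile = OculomotorProfile(),
                    behavior: TimingBehavior = TimingBehavior(),
                    seed: int = 0,
                    block_types: tuple[str, ...] = ("inversion", "main"),
                    include_traces: bool = False,
                    max_trials_per_subject: int | None = None):
    """Simulate a tidy cohort dataset over full experimental plans.

    Per-subject gain intercepts are Normal(0, subject_intercept_sd) and
    per-trial gain noise Normal(0, trial_noise_sd); the per-trial gain
    is the gravity-specific true gain plus both.  Responses follow
    ``behavior`` with the central predictor anchored at the cohort-mean
    occluded duration of the trial's block type.

    Returns a DataFrame (one row per trial) or, with ``include_traces``,
    a tuple ``(frame, traces, truths)`` where the trace list carries the
    simulated raw gaze of every trial retained.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(n_subjects)
    rng_master = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    picked: list[tuple[int, TrialCondition, float]] = []
    for i in range(n_subjects):
        srng = np.random.default_rng(subj_seeds[i])
        b_i = float(srng.normal(0.0, profile.subject_intercept_sd))
        plan = build_experiment(f"s{i + 1}", inversion_first=(i % 2 == 0),
                                seed=int(subj_seeds[i].generate_state(1)[0] % 2**31))
        trials = [tc for tc in plan.trials if tc.block_type in block_types]
        if max_trials_per_subject is not None:
            trials = trials[:max_trials_per_subject]
        for tc in trials:
            gain = (profile.gain_for(tc.gravity_mult) + b_i
                    + float(srng.normal(0.0, profile.trial_noise_sd)))
            picked.append((i, tc, gain))

    # central predictor: cohort-mean occluded duration per block type
    durs: dict[str, list[float]] = {}
    cache: dict[tuple, tuple[float, float]] = {}
    for i, tc, gain in picked:
        params = condition_params(tc)
        key = (tc.gravity_mult, tc.v_xi, tc.v_yi, round(tc.occ_fraction, 12))
        if key not in cache:
            T = traj.return_time(params)
            cache[key] = (T, traj.occlusion_onset(params, tc.occ_fraction))
        T, t_occ = cache[key]
        durs.setdefault(tc.block_type, []).append(T - t_occ)
    central = {bt: float(np.mean(v)) for bt, v in durs.items()}

    traces, truths = [], []
    for i, tc, gain in picked:
        params = condition_params(tc)
        key = (tc.gravity_mult, tc.v_xi, tc.v_yi, round(tc.occ_fraction, 12))
        T, t_occ = cache[key]
        t_resp = simulate_response(tc, behavior, rng_master,
                                   central_duration=central[tc.block_type])
        rows.append(dict(subject=f"s{i + 1}", block_type=tc.block_type,
                         gravity_mult=tc.gravity_mult, v_xi=tc.v_xi,
                         v_yi=tc.v_yi, occ_category=tc.occ_category,
                         occ_fraction=tc.occ_fraction,
                         trial_index=tc.trial_index, gain=gain,
                         t_occ=t_occ, t_coincidence=T,
                         occluded_duration=T - t_occ, t_response=t_resp))
        if include_traces:
            trace, truth = simulate_trial_gaze(tc, profile, rng_master,
                                               gain_trial=gain,
                                               return_truth=True)
            trace.trial_id = f"s{i + 1}_{trace.trial_id}"
            traces.append(trace)
            truths.append(truth)

    frame = pd.DataFrame(rows)
    if include_traces:
        return frame, traces, truths
    return frame
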