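"""Self-validation computations: oracle comparisons and recovery studies.

Shared by the test suite and the desk-check script.  Every function
recomputes its quantity from scratch by running the package's own
pipeline on freshly generated synthetic data, against an independent
oracle where one exists (adaptive ODE integration for the drag
kinematics, bracketed root finding for the extrapolation formula).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from . import pipeline as P
from . import synthetic as S
from . import timing as TM
from . import trajectory as traj
from .design import TrialCondition
from .stats import analyze_gain, power_simulation
from .synthetic import OculomotorProfile, TimingBehavior, simulate_cohort

DESIGN_CELLS = [(g, vy, vx)
                for g in (0.7, 0.85, 1.0, 1.15, 1.3, -1.0)
                for vy in (4.5, 6.0)
                for vx in (3.0, 4.0)]


def _condition(g, vx, vy, occ_category="long", occ_fraction=0.475):
    return TrialCondition(1, "main", g, vx, vy, occ_category, occ_fraction, 0, 0)


def _target_speed(params):
    return lambda t: traj.speed(params, np.clip(np.asarray(t, float), 0, None))


# ---------------------------------------------------------------------------
# trajectory oracles

def trajectory_vs_ode_max_error() -> float:
    """Max |closed form - adaptive ODE| (m) over the full design."""
    worst = 0.0
    for g, vy, vx in DESIGN_CELLS:
        p = traj.params_for(g, vx, vy)

        def rhs(_t, s):
            k = p.c / p.m
            return [s[2], s[3], -k * s[2], -p.sign * p.g - k * s[3]]

        T = traj.return_time(p)
        ts = np.linspace(1e-3, T, 20)
        sol = solve_ivp(rhs, (0, T), [p.start_x, p.start_y, p.v_xi,
                                      p.sign * p.v_yi],
                        t_eval=ts, rtol=1e-11, atol=1e-13)
        st = traj.position(p, ts)
        worst = max(worst, float(np.max(np.hypot(st.x - sol.y[0],
                                                 st.y - sol.y[1]))))
    return worst


def ballistic_limit_max_error() -> float:
    """Max |drag solution at c->0 - ballistic closed form| (m)."""
    worst = 0.0
    for g, vy, vx in DESIGN_CELLS:
        pb = traj.make_params(g, vx, vy, c=0.0)
        pe = traj.make_params(g, vx, vy, c=1e-10)
        ts = np.linspace(0, traj.return_time(pb), 50)
        sb, se = traj.position(pb, ts), traj.position(pe, ts)
        worst = max(worst, float(np.max(np.hypot(sb.x - se.x, sb.y - se.y))))
    return worst


def ttc_vs_bisection_max_error(n_grid: int = 100, seed: int = 0) -> float:
    """Max |closed-form extrapolation - bisection root| (s) on a grid."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_grid):
        v = float(rng.uniform(-8, 8))
        d = float(rng.uniform(0.01, 5.0))
        got = traj.predict_ttc_1g(traj.TtcQuery(v, d))
        root = bisect(lambda t: 4.905 * t * t - v * t - d, 1e-12, 20.0,
                      xtol=1e-12)
        worst = max(worst, abs(got - root))
    return worst


# ---------------------------------------------------------------------------
# pipeline recovery

def gain_recovery_max_cell_error(gain_true: float = 0.9,
                                 trials_per_cell: int = 4,
                                 noise_sd: float = 0.005,
                                 dropout: float = 0.064,
                                 seed: int = 0) -> float:
    """Max |recovered cell-mean gain - true gain| over all 24 cells."""
    prof = OculomotorProfile(gain_true=gain_true, pos_noise_sd=noise_sd,
                             dropout_rate=dropout)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for g, vy, vx in DESIGN_CELLS:
        cond = _condition(g, vx, vy)
        params = S.condition_params(cond)
        gains = []
        for _ in range(trials_per_cell):
            trace, truth = S.simulate_trial_gaze(cond, prof, rng,
                                                 return_truth=True)
            res = P.process_trace(trace, _target_speed(params), truth.t_occ)
            if res.summary.valid:
                gains.append(res.summary.gain)
        worst = max(worst, abs(float(np.mean(gains)) - gain_true))
    return worst


def saccade_onset_recovery(seed: int = 0) -> tuple[float, int]:
    """(max |onset error| in samples over isolated ~2 deg injections,
    number of false-positive segments on sub-threshold pursuit)."""
    worst = 0.0
    for g, vy, vx in DESIGN_CELLS:
        cond = _condition(g, vx, vy)
        prof = OculomotorProfile(gain_true=0.75, pos_noise_sd=0.0,
                                 dropout_rate=0.0, catchup_threshold=np.inf,
                                 predictive_saccade=False,
                                 scheduled_saccades=(0.42,))
        trace, truth = S.simulate_trial_gaze(cond, prof, seed,
                                             return_truth=True)
        params = S.condition_params(cond)
        res = P.process_trace(trace, _target_speed(params), truth.t_occ)
        det = [s.onset_t for s in res.segments if s.onset_t > 0.3]
        inj = [s[0] for s in truth.saccades if s[0] > 0.3]
        if len(det) != 1 or len(inj) != 1:
            worst = max(worst, np.inf)
            continue
        worst = max(worst, abs(round((det[0] - inj[0]) * 200.0)))

    false_pos = 0
    for gain in (1.0, 1.2):
        prof = OculomotorProfile(gain_true=gain, pursuit_latency=0.0,
                                 pos_noise_sd=0.0, dropout_rate=0.0,
                                 catchup_threshold=np.inf,
                                 predictive_saccade=False)
        cond = _condition(1.0, 3.0, 6.0)
        trace, truth = S.simulate_trial_gaze(cond, prof, seed,
                                             return_truth=True)
        params = S.condition_params(cond)
        res = P.process_trace(trace, _target_speed(params), truth.t_occ,
                              fallback_start=0.0)
        false_pos += len(res.segments)
    return worst, false_pos


# ---------------------------------------------------------------------------
# effect recovery and calibration

GAIN_DEFICIT = 0.13  # generated -1 g pursuit-gain deficit


def inversion_effect_recovery(seed: int = 0) -> tuple[float, float]:
    """(estimated -1 g gain contrast, LRT p) for a 10-subject cohort
    generated with a 0.13 gain deficit at the full inversion-block size."""
    gains = {1.0: 0.9, -1.0: 0.9 - GAIN_DEFICIT, 0.7: 0.9, 0.85: 0.9,
             1.15: 0.9, 1.3: 0.9}
    df = simulate_cohort(10, OculomotorProfile(gain_true=gains),
                         TimingBehavior(), seed=seed,
                         block_types=("inversion",))
    rep = analyze_gain(df, "inversion")
    term = [k for k in rep.full.fixed_effects if "-1.0" in k][0]
    return rep.full.fixed_effects[term][0], rep.lrt_vs_null.p


def null_rejection_rate(n_sims: int = 500, seed: int = 0) -> float:
    """Type-I rate of the LMM + LRT pipeline under a null generator."""
    return power_simulation(n_subjects=10, n_trials=24, effect=0.0,
                            n_sims=n_sims, seed=seed)


# ---------------------------------------------------------------------------
# timing-model discrimination

def model_discrimination_rate(n_cohorts: int = 200, seed: int = 0) -> float:
    """Fraction of cohorts whose generating timing rule (earth-gravity
    extrapolation vs central tendency) is identified by the higher
    observed-predicted correlation."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_cohorts)]
    hits = 0
    for i, s in enumerate(seeds):
        lam = 0.0 if i % 2 == 0 else 1.0
        beh = TimingBehavior(lambda_central=lam)
        df = simulate_cohort(4, OculomotorProfile(), beh, seed=s,
                             block_types=("main",),
                             max_trials_per_subject=160)
        res = TM.compare_models(TM.add_timing_columns(df))
        truth = "predicted_1g" if lam == 0.0 else "predicted_central"
        hits += res["best_predictor"] == truth
    return hits / n_cohorts


def sign_pattern_cells_correct(seed: int = 0) -> tuple[int, int]:
    """(cells with the expected error sign, total cells) for an
    earth-gravity-extrapolation cohort: early for 0.7/0.85 g, late for
    1.15/1.3 g, in both occlusion categories."""
    df = simulate_cohort(10, OculomotorProfile(),
                         TimingBehavior(lambda_central=0.0), seed=seed,
                         block_types=("main",))
    df = TM.add_timing_columns(df)
    cells = df.groupby(["gravity_mult", "occ_category"])["corrected_error"] \
        .mean()
    expected = {0.7: -1, 0.85: -1, 1.15: 1, 1.3: 1}
    total = correct = 0
    for (g, _occ), mean_err in cells.items():
        if g not in expected:
            continue
        total += 1
        correct += int(np.sign(mean_err) == expected[g])
    return correct, total
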