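"""Synthetic gaze/response generator: round trips and statistical structure."""

import numpy as np
import pytest

from gravipursuit import pipeline as P
from gravipursuit import synthetic as S
from gravipursuit import trajectory as traj

from conftest import DESIGN_CELLS, make_condition, target_speed_fn


def recover_gain(cond, profile, seed=0):
    trace, truth = S.simulate_trial_gaze(cond, profile, seed, return_truth=True)
    params = S.condition_params(cond)
    res = P.process_trace(trace, target_speed_fn(params), truth.t_occ)
    return res, truth


class TestTrialGaze:
    def test_perfect_pursuit_recovers_gain_one(self):
        prof = S.OculomotorProfile(gain_true=1.0, pos_noise_sd=0.0,
                                   dropout_rate=0.0,
                                   catchup_threshold=np.inf)
        res, _ = recover_gain(make_condition(), prof)
        assert res.summary.gain == pytest.approx(1.0, abs=0.01)

    def test_fractional_gain_round_trip(self):
        prof = S.OculomotorProfile(gain_true=0.8, pos_noise_sd=0.0,
                                   dropout_rate=0.0)
        res, _ = recover_gain(make_condition(), prof)
        assert res.summary.gain == pytest.approx(0.8, abs=0.01)

    def test_round_trip_across_design_cells(self):
        prof = S.OculomotorProfile(gain_true=0.85, pos_noise_sd=0.0,
                                   dropout_rate=0.0)
        for g, vy, vx in DESIGN_CELLS:
            res, _ = recover_gain(make_condition(g, vx, vy), prof)
            assert res.summary.gain == pytest.approx(0.85, abs=0.01), (g, vy, vx)

    def test_dropout_fraction_matches_rate(self):
        prof = S.OculomotorProfile(dropout_rate=0.064)
        n_low = n_tot = 0
        for seed in range(40):
            trace = S.simulate_trial_gaze(make_condition(), prof, seed)
            n_low += int((trace.confidence < 0.9).sum())
            n_tot += len(trace)
        frac = n_low / n_tot
        ci = 3 * np.sqrt(0.064 * 0.936 / n_tot)
        assert abs(frac - 0.064) < ci

    def test_sampling_rate_and_monotone_time(self):
        trace = S.simulate_trial_gaze(make_condition(), S.OculomotorProfile(), 0)
        assert np.allclose(np.diff(trace.t), 1 / 200.0)

    def test_same_seed_identical_trace(self):
        prof = S.OculomotorProfile()
        a = S.simulate_trial_gaze(make_condition(), prof, 7)
        b = S.simulate_trial_gaze(make_condition(), prof, 7)
        assert np.array_equal(a.x_surf, b.x_surf)
        assert np.array_equal(a.confidence, b.confidence)

    def test_injected_saccade_speed_exceeds_ratio_threshold(self):
        prof = S.OculomotorProfile(gain_true=0.8, pos_noise_sd=0.0,
                                   dropout_rate=0.0)
        cond = make_condition()
        trace, truth = S.simulate_trial_gaze(cond, prof, 0, return_truth=True)
        params = S.condition_params(cond)
        x, y = P.map_to_scene(trace.x_surf, trace.y_surf)
        for onset, offset in truth.saccades[:2]:
            i0 = int(np.searchsorted(trace.t, onset))
            i1 = int(np.searchsorted(trace.t, offset))
            mid = (i0 + i1) // 2
            eye_speed = (np.hypot(x[mid + 1] - x[mid - 1], y[mid + 1] - y[mid - 1])
                         / (trace.t[mid + 1] - trace.t[mid - 1]))
            target = traj.speed(params, trace.t[mid])
            assert eye_speed > 1.5 * target


class TestSaccadeRecovery:
    def test_isolated_injection_recovered_within_two_samples(self):
        # ~2 deg amplitude scheduled saccade on sub-threshold pursuit
        for g, vy, vx in DESIGN_CELLS[:8]:
            cond = make_condition(g, vx, vy)
            prof = S.OculomotorProfile(gain_true=0.75, pos_noise_sd=0.0,
                                       dropout_rate=0.0,
                                       catchup_threshold=np.inf,
                                       predictive_saccade=False,
                                       scheduled_saccades=(0.42,))
            res, truth = recover_gain(cond, prof)
            detected = [s for s in res.segments if s.onset_t > 0.3]
            injected = [s for s in truth.saccades if s[0] > 0.3]
            assert len(detected) == 1 and len(injected) == 1
            err = (detected[0].onset_t - injected[0][0]) / (1 / 200.0)
            assert abs(err) <= 2

    def test_zero_false_positives_below_thresholds(self):
        for gain in (1.0, 1.2):
            prof = S.OculomotorProfile(gain_true=gain, pursuit_latency=0.0,
                                       pos_noise_sd=0.0, dropout_rate=0.0,
                                       catchup_threshold=np.inf,
                                       predictive_saccade=False)
            res, _ = recover_gain(make_condition(), prof)
            assert res.segments == []


class TestResponses:
    def test_earth_gravity_observer_on_1g_ballistic_is_exact(self):
        cond = make_condition(gravity=1.0)
        beh = S.TimingBehavior(motor_noise_sd=0.0, system_delay=0.0)
        # ballistic stimulus: the model equals the generator exactly
        params = traj.make_params(1.0, cond.v_xi, cond.v_yi, c=0.0)
        t_occ = traj.occlusion_onset(params, cond.occ_fraction)
        ttc = traj.predict_ttc_1g(traj.ttc_query_at(params, t_occ))
        assert t_occ + ttc == pytest.approx(traj.return_time(params), abs=1e-9)
        # drag stimulus via the public generator: error is a few ms at most
        t_resp = S.simulate_response(cond, beh, 0)
        err = t_resp - traj.return_time(S.condition_params(cond))
        assert abs(err) < 0.01

    @pytest.mark.parametrize("gravity,sign", [(0.7, -1), (0.85, -1),
                                              (1.15, 1), (1.3, 1)])
    def test_error_sign_follows_gravity(self, gravity, sign):
        cond = make_condition(gravity=gravity)
        beh = S.TimingBehavior(motor_noise_sd=0.0, system_delay=0.0)
        err = S.simulate_response(cond, beh, 0) - traj.return_time(
            S.condition_params(cond))
        assert np.sign(err) == sign

    def test_pure_central_tendency_definition(self):
        cond = make_condition()
        params = S.condition_params(cond)
        occluded = traj.return_time(params) - traj.occlusion_onset(
            params, cond.occ_fraction)
        beh = S.TimingBehavior(lambda_central=1.0, motor_noise_sd=0.0,
                               system_delay=0.0)
        t_resp = S.simulate_response(cond, beh, 0, central_duration=0.5)
        err = t_resp - traj.return_time(params)
        assert err == pytest.approx(0.5 - occluded, abs=1e-12)

    def test_central_requires_mean_duration(self):
        with pytest.raises(ValueError):
            S.simulate_response(make_condition(),
                                S.TimingBehavior(lambda_central=0.5), 0)


class TestCohort:
    def test_fixed_seed_reproducible(self):
        a = S.simulate_cohort(3, seed=5, block_types=("inversion",),
                              max_trials_per_subject=60)
        b = S.simulate_cohort(3, seed=5, block_types=("inversion",),
                              max_trials_per_subject=60)
        assert a.equals(b)

    def test_minimum_subjects_enforced(self):
        with pytest.raises(ValueError):
            S.simulate_cohort(1, seed=0)

    def test_gain_variance_structure(self):
        prof = S.OculomotorProfile(subject_intercept_sd=0.05,
                                   trial_noise_sd=0.3)
        df = S.simulate_cohort(12, prof, seed=3, block_types=("inversion",))
        within = df.groupby("subject")["gain"].std().mean()
        between = df.groupby("subject")["gain"].mean().std()
        assert within == pytest.approx(0.3, rel=0.1)
        # between-subject spread of means ~ sqrt(sd_b^2 + sd_w^2/n)
        n = df.groupby("subject").size().iloc[0]
        expected = np.sqrt(0.05**2 + 0.3**2 / n)
        assert between == pytest.approx(expected, rel=0.6)

    def test_zero_intercept_sd_shrinks_between_subject_spread(self):
        prof = S.OculomotorProfile(subject_intercept_sd=0.0,
                                   trial_noise_sd=0.15)
        df = S.simulate_cohort(10, prof, seed=3, block_types=("inversion",))
        between = df.groupby("subject")["gain"].mean().std()
        n = df.groupby("subject").size().iloc[0]
        assert between < 3 * 0.15 / np.sqrt(n)

    def test_observed_vs_predicted_correlation_approaches_one(self):
        from gravipursuit.timing import add_timing_columns, compare_models
        beh = S.TimingBehavior(lambda_central=0.0, motor_noise_sd=0.002)
        df = S.simulate_cohort(4, S.OculomotorProfile(), beh, seed=2,
                               block_types=("main",),
                               max_trials_per_subject=200)
        res = compare_models(add_timing_columns(df))
        assert res["correlations"]["predicted_1g"]["overall"] > 0.99
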