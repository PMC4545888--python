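"""Integration-engine tests: determinism, numerics, and invariants."""

import numpy as np
import pandas as pd
import pytest

from covertsearch.model_core import (
    FIXED,
    LipTopology,
    TrialCondition,
    condition_inputs,
    drift,
)
from covertsearch.sde_engine import (
    EngineOptions,
    _drift_nb,
    _params_vector,
    simulate_batch,
    simulate_trial,
)

COND = TrialCondition(4, "R1", "E_right")


def _zero_noise(params):
    return params.replace(c_lip=0.0, c_it=0.0, c_maip=0.0)


class TestKernelAgreesWithReferenceDrift:
    def test_drift_values_match(self, p11, p12):
        rng = np.random.default_rng(7)
        for params in (p11, p12):
            pv = _params_vector(params)
            W = LipTopology.inhibition_matrix(
                params.eta_lip, params.eta_lip_decay1, params.eta_lip_decay2)
            ins = condition_inputs(params, COND)
            for t in (0.0, 30.0, 90.0, 400.0):
                for _ in range(10):
                    x = rng.uniform(0.0, 0.25, 20)
                    f_ref, _ = drift(x, params, COND, t)
                    f_nb = np.zeros(20)
                    _drift_nb(x, t, pv, W, ins["i_per"], ins["i_tar"],
                              ins["i_ori"], True, f_nb)
                    np.testing.assert_allclose(f_nb, f_ref, rtol=1e-8,
                                               atol=1e-12)

    def test_zero_noise_trajectory_matches_python_heun(self, p11):
        """A short kernel run reproduces a hand-rolled Heun integration."""
        params = _zero_noise(p11)
        opts = EngineOptions(t_max=100.0, traj_t_max=100.0,
                             traj_sample_ms=0.5)
        tr = simulate_trial(params, COND, seed=0, options=opts,
                            record_trajectory=True)
        x = np.zeros(20)
        dt = opts.dt
        ref = [x.copy()]
        for k in range(200):
            t = k * dt
            f1, _ = drift(x, params, COND, t)
            xp = np.clip(x + dt * f1, None, None)
            xp[16:20] = np.maximum(xp[16:20], 0.0)
            xp[18:20] = np.minimum(xp[18:20], FIXED.motor_cap)
            f2, _ = drift(xp, params, COND, t + dt)
            x = x + 0.5 * dt * (f1 + f2)
            x[16:20] = np.maximum(x[16:20], 0.0)
            x[18:20] = np.minimum(x[18:20], FIXED.motor_cap)
            ref.append(x.copy())
        np.testing.assert_allclose(tr.trajectory, np.array(ref), rtol=1e-7,
                                   atol=1e-10)


class TestDeterminism:
    def test_zero_noise_identical_across_seeds(self, p11):
        params = _zero_noise(p11)
        a = simulate_trial(params, COND, seed=1)
        b = simulate_trial(params, COND, seed=999)
        assert a.rt_ms == b.rt_ms
        assert a.response_side == b.response_side

    def test_fixed_master_seed_gives_bit_identical_batches(self, p11):
        conds = [COND, TrialCondition(4, "L1", "E_right")]
        b1 = simulate_batch(p11, conds, 50, seed=123)
        b2 = simulate_batch(p11, conds, 50, seed=123)
        pd.testing.assert_frame_equal(b1.trials, b2.trials)
        b3 = simulate_batch(p11, conds, 50, seed=124)
        assert not b1.trials["rt_ms"].equals(b3.trials["rt_ms"])


class TestNumerics:
    def test_halving_dt_moves_zero_noise_crossing_under_1ms(self, p11):
        params = _zero_noise(p11)
        t_half = simulate_trial(params, COND, seed=0,
                                options=EngineOptions(dt=0.25)).crossing_time_ms
        t_full = simulate_trial(params, COND, seed=0).crossing_time_ms
        assert abs(t_half - t_full) < 1.0

    def test_unreachable_threshold_times_out(self, p11):
        params = p11.replace(theta=FIXED.motor_cap + 0.01)
        tr = simulate_trial(params, COND, seed=3,
                            options=EngineOptions(t_max=400.0,
                                                  traj_t_max=400.0))
        assert tr.timed_out and tr.response_side == "none"
        assert np.isnan(tr.rt_ms)

    def test_motor_activities_respect_cap(self, p11):
        # crank noise and drive to stress the cap
        params = p11.replace(c_maip=3.0, w_aipm=20.0,
                             theta=FIXED.motor_cap + 0.01)
        opts = EngineOptions(t_max=500.0, traj_t_max=500.0)
        for seed in range(5):
            tr = simulate_trial(params, COND, seed=seed, options=opts,
                                record_trajectory=True)
            motor = tr.trajectory[:, 18:20]
            assert motor.max() <= FIXED.motor_cap + 1e-12
            assert motor.min() >= 0.0

    def test_rt_includes_nondecision_time(self, p11):
        tr = simulate_trial(_zero_noise(p11), COND, seed=0)
        assert tr.rt_ms == pytest.approx(tr.crossing_time_ms + p11.t_0)


class TestModelBehavior:
    def test_zero_noise_congruent_right_target_responds_right(self, p11,
                                                              p12):
        """Deterministic skeleton: only rightward drive on a congruent
        right-facing-target trial, so any crossing is by the R motor unit.
        M11's skeleton crosses threshold; M12's peaks just below it (its
        crossings are noise-assisted), but its motor drive is still
        strictly rightward."""
        opts = EngineOptions(t_max=3000.0, traj_t_max=3000.0)
        tr = simulate_trial(_zero_noise(p11), COND, seed=0, options=opts)
        assert tr.response_side == "R"
        assert tr.correct
        tr12 = simulate_trial(_zero_noise(p12), COND, seed=0, options=opts,
                              record_trajectory=True)
        motor = tr12.trajectory[:, 18:20]
        assert motor[:, 1].max() > 0.9 * p12.theta
        assert motor[:, 1].max() > motor[:, 0].max()

    def test_mirrored_condition_mirrors_zero_noise_outcome(self, p11):
        params = _zero_noise(p11)
        tr_r = simulate_trial(params, TrialCondition(4, "R1", "E_right"),
                              seed=0)
        tr_l = simulate_trial(params, TrialCondition(4, "L1", "E_left"),
                              seed=0)
        assert tr_r.response_side == "R" and tr_l.response_side == "L"
        # identical up to floating-point summation order (one step at most)
        assert abs(tr_r.rt_ms - tr_l.rt_ms) <= 0.5

    def test_ou_input_stationary_moments(self, p11):
        """The LIP input OU process reaches mean I and variance c^2/(2 tau)
        under the literal noise convention."""
        params = p11.replace(c_it=0.0, c_maip=0.0, c_lip=1.4,
                             s_lip=0.4, s_tar=0.3, s_back=0.5,
                             theta=10.0)  # unreachable: run to t_max
        opts = EngineOptions(t_max=60000.0, traj_t_max=60000.0)
        tr = simulate_trial(params, COND, seed=11, options=opts,
                            record_trajectory=True)
        rho = tr.trajectory[:, 9]  # OU input of unit R1 (perceptual+target)
        t = tr.trajectory_t
        sample = rho[t > 1000.0]
        expected_mean = 0.4 + 0.3 + 0.5
        expected_var = 1.4 ** 2 / (2.0 * FIXED.tau_lip_noise)
        assert sample.mean() == pytest.approx(expected_mean, rel=0.01)
        assert sample.var() == pytest.approx(expected_var, rel=0.05)

    def test_batch_counts_and_summaries(self, p11):
        conds = [COND, TrialCondition(4, "L1", "E_right")]
        batch = simulate_batch(p11, conds, 300, seed=5)
        assert len(batch.trials) == 600
        done = batch.completed()
        assert batch.accuracy() == pytest.approx(done["correct"].mean())
        assert set(batch.trials["congruent"].unique()) == {True, False}
        # RTs split by correctness partition the completed trials
        n_c = len(batch.rts(correct=True))
        n_e = len(batch.rts(correct=False))
        assert n_c + n_e == len(done)

    def test_trajectory_recording_window(self, p11):
        opts = EngineOptions(t_max=1000.0, traj_t_max=300.0)
        batch = simulate_batch(p11, [COND], 20, seed=2, options=opts,
                               record_trajectories=True)
        tr = batch.traces[COND]
        assert tr.time_ms[-1] == pytest.approx(300.0)
        assert tr.mean.shape == (20, 301)
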