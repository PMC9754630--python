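"""Observer simulators, motor filter, reward-rate estimation, tuning."""

import numpy as np
import pandas as pd
import pytest

from dynthresh.beliefs import llr_to_likelihood
from dynthresh.contexts import make_reward_change_schedule, make_static_schedule, make_tokens_context
from dynthresh.simulate import (
    ConstParams,
    NBParams,
    UGMParams,
    apply_motor_filter,
    estimate_reward_rate,
    generate_evidence_streams,
    noise_strength,
    simulate_const_trial,
    simulate_tokens_trials,
    simulate_trials,
    tune_heuristic,
)
from dynthresh.solver import extract_thresholds, solve_reward_rate


class TestMotorFilter:
    def test_zero_noise_is_identity(self, rng):
        rt = np.array([0.1, 0.4, 0.9])
        assert np.array_equal(apply_motor_filter(rt, 0.0, (0.0, 1.0), rng), rt)

    def test_all_outputs_inside_window(self, rng):
        rt = np.full(100_000, 0.02)
        out = apply_motor_filter(rt, 0.2, (0.0, 1.0), rng)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_sd_approaches_sigma_in_wide_window(self, rng):
        rt = np.full(200_000, 50.0)
        out = apply_motor_filter(rt, 0.1, (0.0, 100.0), rng)
        assert out.std() == pytest.approx(0.1, rel=0.02)
        assert out.mean() == pytest.approx(50.0, abs=0.01)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_motor_filter([0.5], -0.1, (0.0, 1.0), rng)


class TestRewardRateEstimate:
    def test_deterministic_trials_arithmetic(self, static_context):
        # reward R = 4, Td = 0.5, cost c = 1, ti = 1 -> (4 - 0.5)/(0.5 + 1)
        df = pd.DataFrame({
            "rt_observed": [0.5, 0.5], "reward": [4.0, 4.0],
        })
        rho, se = estimate_reward_rate(df, static_context)
        assert rho == pytest.approx((4.0 - 0.5) / 1.5)
        assert se == pytest.approx(0.0)

    def test_zero_reward_zero_cost(self):
        from dynthresh.contexts import BaseSettings, make_static_schedule

        ctx = make_static_schedule(BaseSettings(cost=0.0))
        df = pd.DataFrame({"rt_observed": [0.2, 0.4], "reward": [0.0, 0.0]})
        rho, _ = estimate_reward_rate(df, ctx)
        assert rho == 0.0

    def test_requires_two_trials(self, static_context):
        with pytest.raises(ValueError):
            estimate_reward_rate(pd.DataFrame({"rt_observed": [0.1], "reward": [1.0]}),
                                 static_context)


class TestNoisyBayesian:
    def test_matches_solver_reward_rate(self, static_context):
        sol = solve_reward_rate(static_context)
        trace = extract_thresholds(sol)
        df = simulate_trials(NBParams(5.0, 1.0), static_context, 100_000,
                             rng=np.random.default_rng(3), thresholds=trace)
        rho, se = estimate_reward_rate(df, static_context)
        assert abs(rho - sol.rho) < 3 * se

    def test_no_responses_while_thresholds_infinite(self, low_to_high_context):
        trace = extract_thresholds(solve_reward_rate(low_to_high_context))
        df = simulate_trials(NBParams(3.0, 1.0), low_to_high_context, 20_000,
                             rng=np.random.default_rng(4), thresholds=trace)
        assert df["rt_raw"].min() >= 0.5 - 1e-12

    def test_accuracy_calibrated_to_crossing_belief(self, static_context):
        # oracle: an independent random-walk simulation of the same constant-
        # threshold observer.  In discrete time P(correct | crossing at LLR y)
        # = 1/(1+e^{-y}) exactly, so empirical accuracy must equal the mean
        # calibrated probability at the (overshooting) crossing belief, and it
        # is bounded below by 1/(1+e^{-theta}).
        theta = 1.2
        n, K = 100_000, 100
        m, dt = 5.0, static_context.delta_t
        gen = np.random.default_rng(55)
        states = gen.choice([-1, 1], size=n)
        incr = states[:, None] * m * dt + np.sqrt(2 * m * dt) * gen.standard_normal((n, K))
        y = np.concatenate([np.zeros((n, 1)), np.cumsum(incr, axis=1)], axis=1)
        hit = np.abs(y) >= theta
        first = np.argmax(hit, axis=1)
        crossed = hit[np.arange(n), first]
        y_end = np.where(crossed, y[np.arange(n), first], y[:, -1])
        choice = np.sign(y_end)
        oracle_acc = np.mean(choice == states)
        calibrated = np.mean(llr_to_likelihood(np.abs(y_end)))
        se = np.std(choice == states, ddof=1) / np.sqrt(n)
        assert oracle_acc == pytest.approx(calibrated, abs=3 * se)
        assert oracle_acc >= llr_to_likelihood(theta) - 3 * se

        df = simulate_trials(ConstParams(theta0=theta), static_context, n,
                             rng=np.random.default_rng(5))
        assert df["correct"].mean() == pytest.approx(oracle_acc, abs=3 * np.sqrt(2) * se)

    def test_fixed_seed_reproducible(self, static_context):
        trace = extract_thresholds(solve_reward_rate(static_context))
        a = simulate_trials(NBParams(5.0, 1.0, 0.5, 0.1), static_context, 50,
                            rng=np.random.default_rng(9), thresholds=trace)
        b = simulate_trials(NBParams(5.0, 1.0, 0.5, 0.1), static_context, 50,
                            rng=np.random.default_rng(9), thresholds=trace)
        pd.testing.assert_frame_equal(a, b)


class TestConstAndSharedStreams:
    def test_tiny_threshold_immediate_response(self, static_context):
        # theta0 -> 0: the first observation always crosses (first-possible-
        # response convention: a strictly positive bound cannot fire at y = 0)
        df = simulate_trials(ConstParams(theta0=1e-9), static_context, 100,
                             rng=np.random.default_rng(1))
        assert np.all(df["rt_raw"] == static_context.delta_t)

    def test_const_responds_early_in_low_to_high(self, low_to_high_context):
        df = simulate_trials(ConstParams(theta0=1.0), low_to_high_context, 20_000,
                             rng=np.random.default_rng(2))
        assert (df["rt_raw"] < 0.5).mean() > 0.3

    def test_shared_streams_equal_beliefs_across_models(self, static_context, rng):
        streams = generate_evidence_streams(static_context, 500, rng)
        nb_trace = extract_thresholds(solve_reward_rate(static_context))
        nb = simulate_trials(NBParams(5.0, 1.0), static_context, 500,
                             rng=np.random.default_rng(0), thresholds=nb_trace,
                             streams=streams)
        const = simulate_trials(ConstParams(theta0=50.0), static_context, 500,
                                rng=np.random.default_rng(0), streams=streams)
        # same latent states; differences attributable to thresholds only
        assert np.array_equal(nb["state"], const["state"])

    def test_single_trial_wrapper(self, static_context):
        rec = simulate_const_trial(ConstParams(theta0=1.0), static_context, rng=7)
        assert rec.choice in (-1, 1)
        assert 0.0 <= rec.rt_observed <= static_context.window


class TestUGM:
    def test_filter_relaxes_to_fixed_point(self):
        # constant input p, no noise: E -> (p - 1/2) with time constant tau
        ctx = make_static_schedule()
        params = UGMParams(theta0=100.0, a=1.0, tau=0.1)
        streams = generate_evidence_streams(ctx, 1, np.random.default_rng(0))
        streams.clean_incr[:] = 0.08  # steadily rising belief
        df = simulate_trials(params, ctx, 1, rng=np.random.default_rng(0), streams=streams)
        assert df["rt_raw"].iloc[0] == ctx.window  # bound never reached

    def test_neutral_belief_never_crosses(self):
        ctx = make_static_schedule()
        streams = generate_evidence_streams(ctx, 10, np.random.default_rng(0))
        streams.clean_incr[:] = 0.0
        df = simulate_trials(UGMParams(theta0=0.3, a=1.0, tau=0.2), ctx, 10,
                             rng=np.random.default_rng(0), streams=streams)
        assert np.all(df["rt_raw"] == ctx.window)

    def test_late_mass_versus_const_in_low_to_high(self, low_to_high_context, rng):
        streams = generate_evidence_streams(low_to_high_context, 20_000, rng)
        ugm = simulate_trials(UGMParams(theta0=0.4, a=1.0, tau=0.2),
                              low_to_high_context, 20_000,
                              rng=np.random.default_rng(0), streams=streams)
        const = simulate_trials(ConstParams(theta0=1.0), low_to_high_context, 20_000,
                                rng=np.random.default_rng(0), streams=streams)
        late = 0.9
        assert (ugm["rt_raw"] >= late).mean() > (const["rt_raw"] >= late).mean()


class TestTuning:
    def test_tuned_const_below_solver_optimum(self, static_context):
        sol = solve_reward_rate(static_context)
        grid = [ConstParams(theta0=t) for t in np.linspace(0.3, 3.0, 10)]
        _, best_rho, table = tune_heuristic("const", static_context, grid,
                                            n_trials=4000, rng=np.random.default_rng(1))
        se = float(table["se"].max())
        assert best_rho <= sol.rho + 3 * se

    def test_widening_grid_never_decreases_optimum(self, static_context):
        narrow = [ConstParams(theta0=t) for t in (0.5, 1.0)]
        wide = narrow + [ConstParams(theta0=t) for t in (1.5, 2.0)]
        _, rho_n, _ = tune_heuristic("const", static_context, narrow, 2000,
                                     np.random.default_rng(2))
        _, rho_w, _ = tune_heuristic("const", static_context, wide, 2000,
                                     np.random.default_rng(2))
        assert rho_w >= rho_n - 1e-12

    def test_empty_grid_rejected(self, static_context):
        with pytest.raises(ValueError):
            tune_heuristic("const", static_context, [], 100)


class TestNoiseStrength:
    @pytest.mark.parametrize("sy, smn, expected", [
        (0.0, 0.0, 0.0), (5.0, 0.25, 1.0), (2.5, 0.125, 0.5),
    ])
    def test_values(self, sy, smn, expected):
        assert noise_strength(sy, smn) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            noise_strength(6.0, 0.1)
        with pytest.raises(ValueError):
            noise_strength(1.0, 0.3)


class TestTokensSimulation:
    def test_forced_choice_at_final_step(self):
        # a sequence that never clinches early (alternating moves) cannot
        # cross a huge bound before the forced terminal decision
        ctx = make_tokens_context("slow", 2.0, 0.5)
        seq = np.array([1, -1] * 7 + [1])
        seqs = np.tile(seq, (10, 1))
        df = simulate_tokens_trials(ConstParams(theta0=500.0), seqs, ctx,
                                    rng=np.random.default_rng(0))
        assert np.all(df["rt_bin"] == 15)
        assert np.all(df["choice"] == 1)
        assert np.all(df["correct"])

    def test_clinched_majority_crosses_any_finite_bound(self):
        # an all-up sequence clinches certainty at step 8 (belief LLR infinite)
        ctx = make_tokens_context("slow", 2.0, 0.5)
        seqs = np.ones((5, 15), dtype=int)
        df = simulate_tokens_trials(ConstParams(theta0=500.0), seqs, ctx,
                                    rng=np.random.default_rng(0))
        assert np.all(df["rt_bin"] == 8)

    def test_rewards_and_state_follow_majority(self):
        ctx = make_tokens_context("fast", 3.0, 0.1)
        rng = np.random.default_rng(8)
        seqs = rng.choice([-1, 1], size=(2000, 15))
        df = simulate_tokens_trials(ConstParams(theta0=2.0), seqs, ctx, rng=rng)
        majority = np.where((seqs == 1).sum(axis=1) >= 8, 1, -1)
        assert np.array_equal(df["state"], majority)
        assert set(np.unique(df["reward"])) <= {3.0, -1.0}
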