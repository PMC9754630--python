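"""Backward induction, reward-rate co-optimisation, thresholds, motifs."""

import numpy as np
import pytest

from dynthresh.beliefs import BeliefGrid
from dynthresh.contexts import (
    BaseSettings,
    RewardProcessModel,
    make_inferred_reward_context,
    make_reward_change_schedule,
    make_snr_change_schedule,
    make_static_schedule,
    make_tokens_context,
)
from dynthresh.solver import (
    CHOOSE_MINUS,
    CHOOSE_PLUS,
    WAIT,
    MotifLabel,
    ThresholdTrace,
    backward_induction,
    classify_motif,
    extract_thresholds,
    motif_map,
    solve_inferred_reward,
    solve_reward_rate,
    terminal_value,
)


class TestTerminalValue:
    def test_arithmetic(self, grid, static_context):
        vc, act = terminal_value(grid, static_context, rho=0.0)
        # V(1/2) = max(Rc/2, Rc/2) = 2.5 at Rc=5, Ri=0
        assert vc[grid.center_index] == pytest.approx(2.5)
        # near p=1: Rc - <ti> rho = 5
        assert vc[-1] == pytest.approx(5.0 * grid.points[-1])

    def test_penalty_enters_through_iti(self, grid, static_context):
        vc0, _ = terminal_value(grid, static_context, rho=0.0)
        vc1, _ = terminal_value(grid, static_context, rho=1.0)
        assert np.allclose(vc0 - vc1, 1.0)  # <ti> = 1

    def test_mirror_symmetric(self, grid, static_context):
        vc, act = terminal_value(grid, static_context, rho=0.7)
        assert np.array_equal(vc, vc[::-1])
        assert not np.any(act == WAIT)


class TestBackwardInduction:
    def test_huge_cost_collapses_thresholds(self):
        ctx = make_static_schedule(BaseSettings(cost=1e4))
        sol = solve_reward_rate(ctx)
        trace = extract_thresholds(sol).in_window()
        assert np.allclose(trace.theta_p_upper, 0.5, atol=2e-3)

    def test_reward_equal_punishment_commits_immediately(self, grid):
        # commitment value independent of p; waiting only pays costs
        ctx = make_static_schedule(BaseSettings(reward_correct=4.0, reward_incorrect=4.0))
        sol = backward_induction(ctx, rho=0.0)
        assert not np.any(sol.action[:-1] == WAIT)
        assert np.allclose(sol.value[0], 4.0, atol=1e-9)

    def test_value_symmetry_exact(self, low_to_high_context):
        sol = backward_induction(low_to_high_context, rho=2.0)
        assert np.array_equal(sol.value, sol.value[:, ::-1])

    def test_value_nonincreasing_in_rho(self, static_context):
        v1 = backward_induction(static_context, rho=1.0).value
        v2 = backward_induction(static_context, rho=2.0).value
        assert np.all(v2 <= v1 + 1e-12)

    def test_static_thresholds_constant_in_window(self, static_context):
        trace = extract_thresholds(solve_reward_rate(static_context)).in_window()
        up = trace.theta_p_upper
        assert np.isfinite(up).all()
        assert up.max() - up.min() <= trace.resolution + 1e-12


class TestRewardRate:
    def test_consistency_residual(self, static_context, low_to_high_context):
        for ctx in (static_context, low_to_high_context):
            sol = solve_reward_rate(ctx)
            scale = float(np.max(ctx.reward_correct(ctx.times())))
            assert abs(sol.value_at_start) <= 1e-6 * scale

    def test_monotone_in_reward(self):
        lo = solve_reward_rate(make_reward_change_schedule(3.0, 6.0)).rho
        hi = solve_reward_rate(make_reward_change_schedule(4.0, 7.0)).rho
        assert hi > lo

    def test_tokens_rate_can_be_negative(self):
        sol = solve_reward_rate(make_tokens_context("slow", Rc=0.5, cost=2.0))
        assert sol.rho < 0  # punishment -1 plus heavy cost beats the tiny reward
        assert abs(sol.value_at_start) <= 1e-6


class TestThresholdExtraction:
    def test_symmetry_exact(self, low_to_high_context):
        trace = extract_thresholds(solve_reward_rate(low_to_high_context))
        finite = np.isfinite(trace.theta_p_upper)
        assert np.array_equal(finite, np.isfinite(trace.theta_p_lower) )
        assert np.allclose(trace.theta_p_lower[finite],
                           1.0 - trace.theta_p_upper[finite], atol=0.0)

    def test_low_to_high_waits_until_change(self, low_to_high_context):
        trace = extract_thresholds(solve_reward_rate(low_to_high_context)).in_window()
        pre = trace.theta_p_upper[(trace.times > 0.1) & (trace.times < 0.5)]
        post = trace.theta_p_upper[trace.times >= 0.5]
        assert np.all(np.isinf(pre))
        assert np.all(np.isfinite(post))

    def test_high_to_low_collapses_before_change(self):
        trace = extract_thresholds(solve_reward_rate(make_reward_change_schedule(9.5, 0.5)))
        w = trace.in_window()
        just_before = w.theta_p_upper[(w.times >= 0.45) & (w.times <= 0.5)]
        assert np.min(just_before) <= 0.5 + w.resolution

    def test_horizon_doubling_invariance(self):
        base = BaseSettings()
        doubled = BaseSettings(horizon_factor=10.0)
        t1 = extract_thresholds(solve_reward_rate(make_reward_change_schedule(3, 8, base)))
        t2 = extract_thresholds(solve_reward_rate(make_reward_change_schedule(3, 8, doubled)))
        w1, w2 = t1.in_window(), t2.in_window()
        finite = np.isfinite(w1.theta_p_upper)
        assert np.array_equal(finite, np.isfinite(w2.theta_p_upper))
        assert np.max(np.abs(w1.theta_p_upper[finite] - w2.theta_p_upper[finite])) \
            <= w1.resolution + 1e-12


def _trace(times, upper, resolution=0.002, window=1.0, discrete=False, lead=None):
    upper = np.asarray(upper, dtype=float)
    return ThresholdTrace(np.asarray(times), upper, 1.0 - upper, window,
                          resolution, discrete, lead)


class TestMotifClassifier:
    def test_infinite_then_constant_is_wait_then_respond(self):
        t = np.linspace(0, 1, 101)
        up = np.where(t < 0.5, np.inf, 0.75)
        assert str(classify_motif(_trace(t, up))) == "wait-then-respond"

    def test_monotone_decreasing_to_half_then_collapsed(self):
        t = np.linspace(0, 1, 101)
        up = np.clip(0.8 - 0.6 * t, 0.5, None)
        assert str(classify_motif(_trace(t, up))) == "collapse-to-zero-before-change"

    def test_strictly_decreasing_finite_is_monotone_collapsing(self):
        t = np.linspace(0, 1, 101)
        up = 0.9 - 0.2 * t
        assert str(classify_motif(_trace(t, up))) == "monotone-collapsing"

    def test_shallow_dip(self):
        t = np.linspace(0, 1, 101)
        up = 0.75 - 0.05 * np.exp(-((t - 0.45) / 0.1) ** 2)
        assert str(classify_motif(_trace(t, up))) == "nonmonotone-dip"

    def test_rise_then_infinite_epoch(self):
        t = np.linspace(0, 1, 101)
        up = np.where(t < 0.4, 0.7 + 0.3 * t, np.where(t < 0.5, np.inf, 0.75))
        assert str(classify_motif(_trace(t, up))) == "nonmonotone-mixed" or \
            str(classify_motif(_trace(t, up))) == "nonmonotone-rise"

    def test_all_infinite_raises(self):
        t = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            classify_motif(_trace(t, np.full(11, np.inf)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            MotifLabel("spiral")

    def test_discrete_staircase_rise_counts(self):
        t = np.arange(16) * 0.2
        lead = np.array([np.inf, np.inf, 2, 3, 2, 3, 2, 3, 4, 3, 4, 3, np.inf, np.inf, np.inf, np.inf])
        up = np.where(np.isfinite(lead), 0.8, np.inf)
        tr = _trace(t, up, resolution=1 / 16, window=3.0, discrete=True, lead=lead)
        assert str(classify_motif(tr)) == "nonmonotone-rise"


class TestMotifMapSmoke:
    def test_small_reward_grid_labels(self):
        df = motif_map([2.0, 9.5], [0.5, 8.0], "reward-change")
        assert set(df.columns) >= {"param1", "param2", "label"}
        assert "failed" not in set(df.label)
        assert str(df.set_index(["param1", "param2"]).loc[(2.0, 8.0), "label"]) \
            == "wait-then-respond"
        assert df.set_index(["param1", "param2"]).loc[(9.5, 0.5), "label"] \
            == "collapse-to-zero-before-change"

    def test_tokens_grid_runs_fast(self):
        df = motif_map([1.0, 6.0], [0.0, 2.0], "tokens-slow")
        assert len(df) == 4
        assert "failed" not in set(df.label)


@pytest.fixture(scope="module")
def short_base():
    return BaseSettings(window=0.6)


class TestInferredReward:

    def test_equal_rewards_match_static_task(self, short_base):
        proc = RewardProcessModel(R_high=5.0, R_low=5.0, hazard=0.5, mu_R=1.0, sigma_R=1.0)
        ctx = make_inferred_reward_context(proc, short_base)
        sol2d = solve_inferred_reward(ctx, n_p=101, n_q=41)
        static = make_static_schedule(short_base)
        sol1d = solve_reward_rate(static, grid=BeliefGrid(n_points=101))
        assert sol2d.rho == pytest.approx(sol1d.rho, abs=5e-3)
        # the action map at t=0 must not depend on q when rewards are equal
        # (up to razor-edge ties at the wait/commit boundary)
        a0 = sol2d.action[0]
        assert np.mean(a0 == a0[:, :1]) > 0.99

    def test_pinned_reward_belief_reduces_to_known_reward(self, short_base):
        # h = 0 and strong reward evidence: q races to 0/1; thresholds at the
        # q~1 slice match the static task with Rc = R_high
        proc = RewardProcessModel(R_high=6.0, R_low=1.0, hazard=0.0, mu_R=10.0, sigma_R=1.0)
        ctx = make_inferred_reward_context(proc, short_base)
        sol = solve_inferred_reward(ctx, n_p=101, n_q=41, rho=1.0)
        static_hi = make_static_schedule(
            BaseSettings(window=0.6, reward_correct=6.0))
        sol_hi = backward_induction(static_hi, rho=1.0, grid=BeliefGrid(n_points=101))
        a_slice = sol.action[0][:, -1]  # q near 1
        a_ref = sol_hi.action[0]
        agreement = np.mean(a_slice == a_ref)
        assert agreement > 0.95

    def test_consistency_residual(self, short_base):
        proc = RewardProcessModel(R_high=6.0, R_low=2.0, hazard=1.0, mu_R=2.0, sigma_R=1.0)
        ctx = make_inferred_reward_context(proc, short_base)
        sol = solve_inferred_reward(ctx, n_p=81, n_q=31)
        assert abs(sol.value_at_start) <= 1e-6 * proc.R_high
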