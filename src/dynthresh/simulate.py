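"""Forward simulation of noisy decision models and reward-rate estimation.

Three observer models share the same evidence streams and noise budget and
differ only in their commitment rule:

* **noisy Bayesian (NB)** -- the normative belief, corrupted by sensory
  diffusion ``σ_y dW'``, compared against the DP-derived time-varying
  thresholds ``±θ(t)``;
* **constant-threshold (Const)** -- the same noisy belief against a fixed
  ``±θ0``;
* **urgency-gating (UGM)** -- the state likelihood low-pass filtered,
  ``τ dE = (-E + p - 1/2) dt + σ_y dW``, against a hyperbolically collapsing
  bound ``±θ0/(a t)``.

Measured response times pass through a Gaussian motor filter of width
``σ_mn``, rejection-resampled into the valid response window.  Reward rates
are estimated as ``(⟨R⟩ - c⟨Td⟩) / (⟨Td⟩ + ⟨t_i⟩)`` with a delta-method
standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beliefs import likelihood_to_llr, llr_to_likelihood
from .contexts import (
    TOKENS_TOTAL,
    ContextSchedule,
    TokensState,
    tokens_likelihood,
)
from .solver import ThresholdTrace, extract_thresholds, solve_reward_rate

__all__ = [
    "NBParams",
    "ConstParams",
    "UGMParams",
    "TrialRecord",
    "EvidenceStreams",
    "generate_evidence_streams",
    "simulate_trials",
    "simulate_nb_trial",
    "simulate_const_trial",
    "simulate_ugm_trial",
    "simulate_tokens_trials",
    "tokens_sim_arrays",
    "apply_motor_filter",
    "estimate_reward_rate",
    "tune_heuristic",
    "noise_strength",
    "tokens_likelihood_table",
]

MAX_SIGMA_Y = 5.0
MAX_SIGMA_MN = 0.25


@dataclass(frozen=True)
class NBParams:
    """Noisy Bayesian observer: reward, cost and the two noise strengths."""

    Rc: float
    c: float
    sigma_y: float = 0.0
    sigma_mn: float = 0.0

    def __post_init__(self):
        if self.sigma_y < 0 or self.sigma_mn < 0:
            raise ValueError("noise strengths must be nonnegative")


@dataclass(frozen=True)
class ConstParams:
    """Constant-threshold observer."""

    theta0: float
    sigma_y: float = 0.0
    sigma_mn: float = 0.0

    def __post_init__(self):
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")
        if self.sigma_y < 0 or self.sigma_mn < 0:
            raise ValueError("noise strengths must be nonnegative")


@dataclass(frozen=True)
class UGMParams:
    """Urgency-gating observer: bound scale, gain, filter time constant."""

    theta0: float
    a: float
    tau: float
    sigma_y: float = 0.0
    sigma_mn: float = 0.0

    def __post_init__(self):
        if self.theta0 <= 0 or self.a <= 0 or self.tau <= 0:
            raise ValueError("theta0, a and tau must be positive")
        if self.sigma_y < 0 or self.sigma_mn < 0:
            raise ValueError("noise strengths must be nonnegative")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial."""

    state: int
    choice: int
    rt_raw: float
    rt_observed: float
    correct: bool
    reward_earned: float
    seed: int | None = None


@dataclass
class EvidenceStreams:
    """Shared per-trial stimulus and noise streams for model comparison.

    Using one set of streams across models guarantees that performance
    differences are attributable to the commitment rules alone.
    """

    states: np.ndarray       # (n,) latent states ±1
    clean_incr: np.ndarray   # (n, K) evidence-driven LLR increments
    sensory_z: np.ndarray    # (n, K) standard normals for sensory noise
    delta_t: float

    @property
    def n_trials(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.clean_incr.shape[1]


def generate_evidence_streams(context: ContextSchedule, n_trials: int,
                              rng: np.random.Generator | int | None = None) -> EvidenceStreams:
    """Draw latent states and evidence for ``n_trials`` response-window trials."""
    rng = np.random.default_rng(rng)
    dt = context.delta_t
    n_steps = int(round(context.window / dt))
    t = np.arange(n_steps) * dt
    m_t = 2.0 * np.asarray(context.mu(t), dtype=float) ** 2 / context.sigma**2
    states = rng.choice([-1, 1], size=n_trials)
    z = rng.standard_normal((n_trials, n_steps))
    clean = states[:, None] * m_t[None, :] * dt + np.sqrt(2.0 * m_t * dt)[None, :] * z
    sensory = rng.standard_normal((n_trials, n_steps))
    return EvidenceStreams(states, clean, sensory, dt)


def apply_motor_filter(rt_raw, sigma_mn: float, window: tuple[float, float],
                       rng: np.random.Generator | int | None = None):
    """Gaussian response-time filter with rejection resampling into the window.

    The measured time is ``T̃ ~ N(T, σ_mn²)``, redrawn until it falls inside
    ``window``; with σ_mn = 0 the raw times pass through unchanged.
    """
    if sigma_mn < 0:
        raise ValueError("sigma_mn must be nonnegative")
    rt_raw = np.atleast_1d(np.asarray(rt_raw, dtype=float))
    lo, hi = window
    if np.any((rt_raw < lo) | (rt_raw > hi)):
        raise ValueError("raw response times must lie inside the window")
    if sigma_mn == 0:
        return rt_raw.copy()
    rng = np.random.default_rng(rng)
    out = rng.normal(rt_raw, sigma_mn)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(rt_raw[bad], sigma_mn)
        bad = (out < lo) | (out > hi)
    return out


def _threshold_series(params, context: ContextSchedule, thresholds: ThresholdTrace | None,
                      t: np.ndarray) -> np.ndarray:
    """Upper LLR threshold evaluated on the simulation time grid."""
    if isinstance(params, NBParams):
        if thresholds is None:
            thresholds = extract_thresholds(solve_reward_rate(context))
        return thresholds.interp_llr_upper(t)
    if isinstance(params, ConstParams):
        return np.full(len(t), params.theta0)
    raise TypeError("threshold series defined only for NB and Const observers")


def simulate_trials(params, context: ContextSchedule, n_trials: int,
                    rng: np.random.Generator | int | None = None,
                    thresholds: ThresholdTrace | None = None,
                    streams: EvidenceStreams | None = None) -> pd.DataFrame:
    """Vectorised trial simulation for any of the three observer models.

    Returns one row per trial with columns (trial, state, choice, rt_raw,
    rt_observed, correct, reward).  Pass precomputed ``streams`` to replay
    the same stimuli through several models.
    """
    rng = np.random.default_rng(rng)
    if streams is None:
        streams = generate_evidence_streams(context, n_trials, rng)
    n, K = streams.n_trials, streams.n_steps
    dt = streams.delta_t
    t_edges = np.arange(K + 1) * dt  # belief exists at steps 0..K
    window = context.window

    if isinstance(params, UGMParams):
        # low-pass filter the state likelihood; bound collapses as θ0/(a t)
        y = np.concatenate([np.zeros((n, 1)), np.cumsum(streams.clean_incr, axis=1)], axis=1)
        p = llr_to_likelihood(y)
        E = np.zeros((n, K + 1))
        for k in range(K):
            dE = (-E[:, k] + p[:, k] - 0.5) * dt + params.sigma_y * np.sqrt(dt) * streams.sensory_z[:, k]
            E[:, k + 1] = E[:, k] + dE / params.tau
        with np.errstate(divide="ignore"):
            bound = params.theta0 / (params.a * t_edges)
        decided = np.abs(E) >= bound[None, :]
        belief = E
    else:
        incr = streams.clean_incr + params.sigma_y * np.sqrt(dt) * streams.sensory_z
        y = np.concatenate([np.zeros((n, 1)), np.cumsum(incr, axis=1)], axis=1)
        theta = _threshold_series(params, context, thresholds, t_edges)
        decided = np.abs(y) >= theta[None, :]
        belief = y

    first = np.argmax(decided, axis=1)
    crossed = decided[np.arange(n), first]
    rt_raw = np.where(crossed, first * dt, window)
    sign_at = np.sign(belief[np.arange(n), np.minimum(first, K)])
    forced_sign = np.sign(belief[:, K])
    choice = np.where(crossed, sign_at, forced_sign)
    ties = choice == 0
    if ties.any():
        choice[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    choice = choice.astype(int)

    rt_obs = apply_motor_filter(rt_raw, params.sigma_mn, (0.0, window), rng)
    correct = choice == streams.states
    # reward is collected when the model commits (rt_raw); the motor filter
    # only jitters the *measured* response time
    Rc_at = np.asarray(context.reward_correct(rt_raw), dtype=float)
    reward = np.where(correct, Rc_at, context.reward_incorrect)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "state": streams.states,
            "choice": choice,
            "rt_raw": rt_raw,
            "rt_observed": rt_obs,
            "correct": correct,
            "reward": reward,
        }
    )


def _single_trial(params, context, rng, thresholds=None) -> TrialRecord:
    seed = int(np.random.default_rng(rng).integers(2**31)) if not isinstance(rng, int) else rng
    df = simulate_trials(params, context, 1, np.random.default_rng(seed), thresholds=thresholds)
    row = df.iloc[0]
    return TrialRecord(int(row.state), int(row.choice), float(row.rt_raw),
                       float(row.rt_observed), bool(row.correct), float(row.reward), seed)


def simulate_nb_trial(params: NBParams, context: ContextSchedule,
                      thresholds: ThresholdTrace, rng=None) -> TrialRecord:
    """One noisy-Bayesian trial against the supplied normative thresholds."""
    return _single_trial(params, context, rng, thresholds=thresholds)


def simulate_const_trial(params: ConstParams, context: ContextSchedule, rng=None) -> TrialRecord:
    """One constant-threshold trial."""
    return _single_trial(params, context, rng)


def simulate_ugm_trial(params: UGMParams, context: ContextSchedule, rng=None) -> TrialRecord:
    """One urgency-gating trial."""
    return _single_trial(params, context, rng)


def estimate_reward_rate(trials: pd.DataFrame, context: ContextSchedule):
    """Reward rate ``(⟨R⟩ - c⟨Td⟩) / (⟨Td⟩ + ⟨t_i⟩)`` with delta-method SE.

    Decision times are the process (commitment) times; the motor filter only
    affects the measured response times, not the economics of the trial.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials to estimate a reward rate")
    td = trials["rt_raw"].to_numpy() if "rt_raw" in trials else trials["rt_observed"].to_numpy()
    if context.kind == "tokens":
        steps = np.rint(td / context.delta_t).astype(int)
        iti = np.asarray(context.iti_by_step)[steps]
        cost = float(context.cost(0.0)) * td
    else:
        iti = np.asarray(context.iti(td), dtype=float)
        # accumulated evidence cost ∫c(t)dt; constant cost in all shipped tasks
        cost = float(context.cost(0.0)) * td
    num = trials["reward"].to_numpy() - cost
    den = td + iti
    A, B = num.mean(), den.mean()
    rho = A / B
    resid = (num - rho * den) / B
    se = resid.std(ddof=1) / np.sqrt(len(trials))
    return rho, se


def tune_heuristic(model_kind: str, context: ContextSchedule, grid,
                   n_trials: int = 4000, rng: np.random.Generator | int | None = None):
    """Grid-search a heuristic model for maximal reward rate (noise-free).

    Every grid cell is evaluated on the *same* evidence streams (common
    random numbers), so the argmax is not driven by sampling noise.  Returns
    ``(best_params, best_rho, table)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty tuning grid")
    rng = np.random.default_rng(rng)
    streams = generate_evidence_streams(context, n_trials, rng)
    filter_seed = int(rng.integers(2**31))
    rows = []
    for params in grid:
        if model_kind == "const" and not isinstance(params, ConstParams):
            raise TypeError("grid entries must be ConstParams")
        if model_kind == "ugm" and not isinstance(params, UGMParams):
            raise TypeError("grid entries must be UGMParams")
        df = simulate_trials(params, context, n_trials,
                             np.random.default_rng(filter_seed), streams=streams)
        rho, se = estimate_reward_rate(df, context)
        rows.append({"params": params, "rho": rho, "se": se})
    table = pd.DataFrame(rows)
    best = table.loc[table["rho"].idxmax()]
    return best["params"], float(best["rho"]), table


def noise_strength(sigma_y: float, sigma_mn: float) -> float:
    """Combined noise strength ``(σ_y + σ_mn) / (σ̄_y + σ̄_mn)`` in [0, 1]."""
    if not (0.0 <= sigma_y <= MAX_SIGMA_Y):
        raise ValueError(f"sigma_y must lie in [0, {MAX_SIGMA_Y}]")
    if not (0.0 <= sigma_mn <= MAX_SIGMA_MN):
        raise ValueError(f"sigma_mn must lie in [0, {MAX_SIGMA_MN}]")
    return (sigma_y + sigma_mn) / (MAX_SIGMA_Y + MAX_SIGMA_MN)


# ---------------------------------------------------------------------------
# Tokens-task simulation
# ---------------------------------------------------------------------------

_P_TABLE = None


def tokens_likelihood_table() -> np.ndarray:
    """P[n, u] = Pr(top wins | u up-moves among the first n); NaN if unreachable."""
    global _P_TABLE
    if _P_TABLE is None:
        tab = np.full((TOKENS_TOTAL + 1, TOKENS_TOTAL + 1), np.nan)
        for n in range(TOKENS_TOTAL + 1):
            for u in range(n + 1):
                tab[n, u] = tokens_likelihood(TokensState(u, n - u, TOKENS_TOTAL - n))
        _P_TABLE = tab
    return _P_TABLE


def simulate_tokens_trials(params, sequences: np.ndarray, context: ContextSchedule,
                           rng: np.random.Generator | int | None = None,
                           thresholds: ThresholdTrace | None = None) -> pd.DataFrame:
    """Simulate an observer on given token sequences (one row per trial).

    ``sequences`` is (n_trials, 15) of ±1 token moves.  Beliefs are evaluated
    at each movement count; the response is the first step at which the noisy
    belief (NB/Const) or filtered urgency signal (UGM) crosses its bound,
    forced at step 15.  Measured times are motor-filtered and snapped back to
    the 16 response bins.
    """
    cols = tokens_sim_arrays(params, sequences, context, rng, thresholds)
    return pd.DataFrame(cols)


def tokens_sim_arrays(params, sequences: np.ndarray, context: ContextSchedule,
                      rng: np.random.Generator | int | None = None,
                      thresholds: ThresholdTrace | None = None) -> dict:
    """Array-only core of :func:`simulate_tokens_trials` (hot path for fitting)."""
    if context.kind != "tokens":
        raise ValueError("tokens simulation needs a tokens context")
    rng = np.random.default_rng(rng)
    seq = np.asarray(sequences)
    n, K = seq.shape
    if K != TOKENS_TOTAL:
        raise ValueError(f"sequences must have {TOKENS_TOTAL} moves")
    dt = context.delta_t
    up = np.concatenate([np.zeros((n, 1), dtype=int), np.cumsum(seq == 1, axis=1)], axis=1)
    p = tokens_likelihood_table()[np.arange(K + 1)[None, :], up]
    y = likelihood_to_llr(np.clip(p, 1e-12, 1 - 1e-12))
    t_steps = np.arange(K + 1) * dt

    if isinstance(params, UGMParams):
        E = np.zeros((n, K + 1))
        z = rng.standard_normal((n, K))
        for k in range(K):
            dE = (-E[:, k] + p[:, k] - 0.5) * dt + params.sigma_y * np.sqrt(dt) * z[:, k]
            E[:, k + 1] = E[:, k] + dE / params.tau
        with np.errstate(divide="ignore"):
            bound = params.theta0 / (params.a * t_steps)
        decided = np.abs(E) >= bound[None, :]
        belief = E
    else:
        noise = params.sigma_y * np.sqrt(dt) * rng.standard_normal((n, K))
        y_noisy = y + np.concatenate([np.zeros((n, 1)), np.cumsum(noise, axis=1)], axis=1)
        if isinstance(params, NBParams):
            if thresholds is None:
                from .contexts import make_tokens_context

                ctx = make_tokens_context(context.speed, Rc=params.Rc, cost=params.c,
                                          Ri=context.reward_incorrect)
                thresholds = extract_thresholds(solve_reward_rate(ctx))
            theta_p = thresholds.policy_p_upper
        else:
            theta_p = llr_to_likelihood(np.full(K + 1, float(params.theta0)))
        # compare in likelihood space so clinched states (p exactly 0 or 1)
        # cross their own boundary despite LLR clipping
        p_noisy = llr_to_likelihood(y_noisy)
        decided = (p_noisy >= theta_p[None, :] - 1e-9) | (p_noisy <= 1.0 - theta_p[None, :] + 1e-9)
        belief = y_noisy

    first = np.argmax(decided, axis=1)
    crossed = decided[np.arange(n), first]
    step = np.where(crossed, first, K)
    sign_at = np.sign(belief[np.arange(n), step])
    choice = sign_at
    ties = choice == 0
    if ties.any():
        choice = choice.copy()
        choice[ties] = rng.choice([-1, 1], size=int(ties.sum()))
    choice = choice.astype(int)

    rt_raw = step * dt
    rt_obs = apply_motor_filter(rt_raw, params.sigma_mn, (0.0, K * dt), rng)
    rt_bin = np.rint(rt_obs / dt).astype(int)
    state = np.where(up[:, K] >= 8, 1, -1)  # realised majority
    correct = choice == state
    Rc = float(context.reward_correct(0.0))
    reward = np.where(correct, Rc, context.reward_incorrect)
    return {
        "trial": np.arange(n),
        "state": state,
        "choice": choice,
        "rt_raw": rt_raw,
        "rt_observed": rt_obs,
        "rt_bin": rt_bin,
        "correct": correct,
        "reward": reward,
    }
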