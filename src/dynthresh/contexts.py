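"""Task environments for dynamic-context 2AFC decisions.

A *context* bundles everything the normative solver needs: the reward for a
correct choice ``Rc(t)`` (possibly time-varying), the punishment ``Ri`` for an
incorrect one, the incremental evidence cost ``c(t)``, the evidence quality
schedule ``μ(t), σ``, the inter-trial interval ``⟨t_i⟩``, and the time
discretisation.  Four families are provided:

* **reward-change** -- ``Rc`` steps from R1 to R2 at t = 0.5;
* **SNR-change** -- drift ``μ`` steps from μ1 to μ2 at t = 0.5;
* **tokens task** -- 15 fair-coin token movements every 200 ms; committing
  early accelerates the remaining animation (slow: 170 ms/move, fast:
  20 ms/move), so the effective inter-trial interval shrinks with decision
  step, acting like a gradually increasing commitment value;
* **inferred reward-change** -- reward alternates between R_H and R_L under a
  two-state Markov process with hazard h, observed only through a second
  Gaussian evidence stream.

Step functions are right-continuous: at a change time the post-change value
already applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binom

from .beliefs import GaussianEvidenceModel

__all__ = [
    "PiecewiseConstant",
    "BaseSettings",
    "ContextSchedule",
    "TokensState",
    "RewardProcessModel",
    "make_reward_change_schedule",
    "make_snr_change_schedule",
    "make_multi_change_schedule",
    "make_static_schedule",
    "tokens_likelihood",
    "tokens_transfer",
    "make_tokens_context",
    "make_inferred_reward_context",
    "load_context",
    "reachable_tokens_states",
    "TOKENS_TOTAL",
    "TOKEN_INTERVAL",
    "POST_DECISION_INTERVAL",
]

#: total number of tokens in the task
TOKENS_TOTAL = 15
#: pre-decision token movement interval (seconds)
TOKEN_INTERVAL = 0.2
#: post-decision animation interval per remaining token (seconds)
POST_DECISION_INTERVAL = {"slow": 0.17, "fast": 0.02}


@dataclass(frozen=True)
class PiecewiseConstant:
    """Right-continuous piecewise-constant function on [0, ∞).

    ``values`` has one more entry than ``breakpoints``; ``value(t)`` returns
    ``values[k]`` for t in ``[breakpoints[k-1], breakpoints[k])``.
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        vals = tuple(float(v) for v in self.values)
        if len(vals) != len(bp) + 1:
            raise ValueError("need exactly one more value than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    def __call__(self, t):
        idx = np.searchsorted(np.asarray(self.breakpoints), np.asarray(t, dtype=float), side="right")
        return np.asarray(self.values)[idx]

    @property
    def is_constant(self) -> bool:
        return len(set(self.values)) == 1

    @staticmethod
    def constant(v: float) -> "PiecewiseConstant":
        return PiecewiseConstant((), (v,))


@dataclass(frozen=True)
class BaseSettings:
    """Shared settings for the continuous-evidence (Gaussian) tasks.

    Defaults follow the single-change task conditions: quality m = 2μ²/σ² = 5
    (σ = 1), constant cost c = 1, punishment Ri = 0, inter-trial interval
    ⟨t_i⟩ = 1, change analysed on a window of 1 time unit with the solver
    horizon extended to 5 windows.
    """

    mu: float = math.sqrt(2.5)  # m = 5 with sigma = 1
    sigma: float = 1.0
    cost: float = 1.0
    reward_correct: float = 5.0
    reward_incorrect: float = 0.0
    iti: float = 1.0
    delta_t: float = 0.01
    window: float = 1.0
    horizon_factor: float = 5.0


@dataclass(frozen=True)
class ContextSchedule:
    """A fully specified decision environment.

    For ``kind == "tokens"`` the time axis is the token-movement index
    (``delta_t`` = 200 ms, ``t_final`` = 3 s) and ``iti_by_step[n]`` gives the
    inter-trial interval when committing after n movements.  For
    ``kind == "inferred-reward"``, ``reward_process`` carries the hidden
    two-state reward dynamics and ``reward_correct`` is unused.
    """

    kind: str  # {"continuous-gaussian", "tokens", "inferred-reward"}
    reward_correct: PiecewiseConstant
    reward_incorrect: float
    cost: PiecewiseConstant
    mu: PiecewiseConstant
    sigma: float
    iti: PiecewiseConstant
    delta_t: float
    t_final: float
    window: float
    speed: str | None = None
    iti_by_step: tuple[float, ...] | None = None
    reward_process: "RewardProcessModel | None" = None

    def __post_init__(self):
        if self.t_final <= 0:
            raise ValueError("t_final must be positive")
        if self.kind not in ("continuous-gaussian", "tokens", "inferred-reward"):
            raise ValueError(f"unknown context kind {self.kind!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.delta_t))

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.delta_t

    def evidence_model(self, t: float) -> GaussianEvidenceModel:
        """Evidence model in force for the observation taken during [t, t+δt)."""
        return GaussianEvidenceModel(mu=float(self.mu(t)), sigma=self.sigma, delta_t=self.delta_t)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the schedule on its native time grid (CSV-friendly)."""
        t = self.times()
        if self.kind == "tokens":
            iti = np.asarray(self.iti_by_step)
        else:
            iti = self.iti(t)
        return pd.DataFrame(
            {
                "t": t,
                "Rc": self.reward_correct(t),
                "mu": self.mu(t),
                "cost": self.cost(t),
                "iti": iti,
            }
        )


def _continuous(base: BaseSettings, reward: PiecewiseConstant, mu: PiecewiseConstant) -> ContextSchedule:
    t_final = base.horizon_factor * base.window
    if t_final <= 0:
        raise ValueError("horizon must be positive")
    return ContextSchedule(
        kind="continuous-gaussian",
        reward_correct=reward,
        reward_incorrect=base.reward_incorrect,
        cost=PiecewiseConstant.constant(base.cost),
        mu=mu,
        sigma=base.sigma,
        iti=PiecewiseConstant.constant(base.iti),
        delta_t=base.delta_t,
        t_final=t_final,
        window=base.window,
    )


def make_static_schedule(base: BaseSettings | None = None) -> ContextSchedule:
    """Static task: constant reward and evidence quality throughout."""
    base = base or BaseSettings()
    return _continuous(
        base,
        PiecewiseConstant.constant(base.reward_correct),
        PiecewiseConstant.constant(base.mu),
    )


def make_reward_change_schedule(R1: float, R2: float, base: BaseSettings | None = None,
                                change_time: float = 0.5) -> ContextSchedule:
    """Reward-change task: ``Rc(t) = (R2-R1)·H(t-0.5) + R1``, punishment Ri = 0."""
    base = base or BaseSettings()
    if not (np.isfinite(R1) and np.isfinite(R2)):
        raise ValueError("rewards must be finite")
    if R1 == R2:
        reward = PiecewiseConstant.constant(R1)
    else:
        reward = PiecewiseConstant((change_time,), (R1, R2))
    return _continuous(base, reward, PiecewiseConstant.constant(base.mu))


def complementary_reward(R1: float, total: float = 11.0) -> float:
    """Post-change reward under the fixed-total constraint R1 + R2 = total."""
    return total - R1


def make_snr_change_schedule(mu1: float, mu2: float, base: BaseSettings | None = None,
                             change_time: float = 0.5) -> ContextSchedule:
    """SNR-change task: ``μ(t) = (μ2-μ1)·H(t-0.5) + μ1`` at fixed reward."""
    base = base or BaseSettings()
    if mu1 < 0 or mu2 < 0:
        raise ValueError("drift magnitudes must be nonnegative")
    if mu1 == mu2:
        mu = PiecewiseConstant.constant(mu1)
    else:
        mu = PiecewiseConstant((change_time,), (mu1, mu2))
    return _continuous(base, mu=mu, reward=PiecewiseConstant.constant(base.reward_correct))


def make_multi_change_schedule(breakpoints, values, which: str,
                               base: BaseSettings | None = None) -> ContextSchedule:
    """Piecewise-constant schedule with several changes in reward or quality.

    Parameters
    ----------
    breakpoints : sequence of change times, strictly increasing, within
        (0, t_final).
    values : sequence of len(breakpoints)+1 piece values.
    which : {"reward", "mu"}
        Which field varies; the other is held at its base value.
    """
    base = base or BaseSettings()
    if len(values) != len(breakpoints) + 1:
        raise ValueError("need one more value than breakpoints")
    pw = PiecewiseConstant(tuple(breakpoints), tuple(values))
    if which == "reward":
        return _continuous(base, pw, PiecewiseConstant.constant(base.mu))
    if which == "mu":
        return _continuous(base, PiecewiseConstant.constant(base.reward_correct), pw)
    raise ValueError("which must be 'reward' or 'mu'")


# ---------------------------------------------------------------------------
# Tokens task
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TokensState:
    """Token counts in the upper, lower, and center targets (U + L + C = 15)."""

    U: int
    L: int
    C: int

    def __post_init__(self):
        if min(self.U, self.L, self.C) < 0:
            raise ValueError("token counts must be nonnegative")
        if self.U + self.L + self.C != TOKENS_TOTAL:
            raise ValueError(f"token counts must sum to {TOKENS_TOTAL}")

    @property
    def n_moved(self) -> int:
        return TOKENS_TOTAL - self.C

    @property
    def lead(self) -> int:
        """Token lead Nt = U - L (positive favours the top target)."""
        return self.U - self.L


def tokens_likelihood(state: TokensState) -> float:
    """Probability that the top target ends with the majority of tokens.

    With C tokens still in the center, the top target wins iff at most
    ``7 - L`` of the remaining coin flips go down, i.e. the binomial(C, 1/2)
    CDF evaluated at ``min(C, 7 - L)``.
    """
    k_max = min(state.C, 7 - state.L)
    if k_max < 0:
        return 0.0
    return float(binom.cdf(k_max, state.C, 0.5))


def tokens_transfer(state: TokensState) -> list[tuple[TokensState, float]]:
    """One token movement: up or down with probability 1/2 each."""
    if state.C == 0:
        raise ValueError("terminal tokens state: no tokens left to move")
    return [
        (TokensState(state.U + 1, state.L, state.C - 1), 0.5),
        (TokensState(state.U, state.L + 1, state.C - 1), 0.5),
    ]


def reachable_tokens_states() -> list[TokensState]:
    """All 136 states reachable from the start (U + L = moves so far)."""
    return [
        TokensState(u, n - u, TOKENS_TOTAL - n)
        for n in range(TOKENS_TOTAL + 1)
        for u in range(n + 1)
    ]


def tokens_iti_by_step(speed: str, base_iti: float = 0.5) -> tuple[float, ...]:
    """Inter-trial interval after committing at movement n (seconds).

    Committing with ``15 - n`` tokens still in the center triggers the
    accelerated animation of the remaining movements, so the effective
    inter-trial interval decreases with n.
    """
    if speed not in POST_DECISION_INTERVAL:
        raise ValueError("speed must be 'slow' or 'fast'")
    step = POST_DECISION_INTERVAL[speed]
    return tuple(base_iti + (TOKENS_TOTAL - n) * step for n in range(TOKENS_TOTAL + 1))


def make_tokens_context(speed: str, Rc: float, cost: float, Ri: float = -1.0,
                        base_iti: float = 0.5) -> ContextSchedule:
    """Tokens-task context for one animation speed and a (reward, cost) pair."""
    iti_steps = tokens_iti_by_step(speed, base_iti)
    return ContextSchedule(
        kind="tokens",
        reward_correct=PiecewiseConstant.constant(Rc),
        reward_incorrect=Ri,
        cost=PiecewiseConstant.constant(cost),
        mu=PiecewiseConstant.constant(0.0),
        sigma=1.0,
        iti=PiecewiseConstant.constant(iti_steps[0]),
        delta_t=TOKEN_INTERVAL,
        t_final=TOKENS_TOTAL * TOKEN_INTERVAL,
        window=TOKENS_TOTAL * TOKEN_INTERVAL,
        speed=speed,
        iti_by_step=iti_steps,
    )


# ---------------------------------------------------------------------------
# Inferred reward-change task
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardProcessModel:
    """Hidden two-state Markov reward process with its evidence stream.

    Reward alternates between ``R_high`` and ``R_low`` with hazard rate ``h``;
    the current state is observed only through Gaussian evidence
    ``η | R_{H/L} ~ N(±μ_R, σ_R²)`` of quality ``m_R = 2μ_R²/σ_R²``.  The
    observer's reward belief ``y_R`` follows the sinh-nonlinearity DDM
    ``dy_R = x(t) m_R dt - 2h sinh(y_R) dt + √(2 m_R) dW``.
    """

    R_high: float
    R_low: float
    hazard: float
    mu_R: float
    sigma_R: float

    def __post_init__(self):
        if self.R_high < self.R_low:
            raise ValueError("R_high must be >= R_low")
        if self.hazard < 0:
            raise ValueError("hazard must be nonnegative")
        if self.sigma_R <= 0:
            raise ValueError("sigma_R must be positive")

    @property
    def m_R(self) -> float:
        return 2.0 * self.mu_R**2 / self.sigma_R**2

    def expected_reward(self, q):
        """Expected reward given reward belief q = Pr(R = R_high)."""
        return self.R_high * np.asarray(q) + self.R_low * (1.0 - np.asarray(q))


def make_inferred_reward_context(proc: RewardProcessModel,
                                 base: BaseSettings | None = None) -> ContextSchedule:
    """Context whose commitment value depends on an inferred reward state."""
    base = base or BaseSettings()
    ctx = _continuous(base, PiecewiseConstant.constant(proc.R_high), PiecewiseConstant.constant(base.mu))
    return ContextSchedule(
        kind="inferred-reward",
        reward_correct=ctx.reward_correct,
        reward_incorrect=base.reward_incorrect,
        cost=ctx.cost,
        mu=ctx.mu,
        sigma=base.sigma,
        iti=ctx.iti,
        delta_t=base.delta_t,
        t_final=ctx.t_final,
        window=base.window,
        reward_process=proc,
    )


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def load_context(path: str | Path) -> ContextSchedule:
    """Read a context from a flat key-value (YAML) config file.

    Recognised keys by kind:

    * ``reward-change``: R1, R2 [, sigma, mu, cost, Ri, ti, delta_t, window]
    * ``snr-change``: mu1, mu2 [, Rc, sigma, cost, Ri, ti, delta_t, window]
    * ``tokens``: speed, Rc, cost [, Ri, base_iti]
    * ``inferred-reward``: RH, RL, h, mR [, sigma_R, ...base keys]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "kind" not in cfg:
        raise ValueError("context config must be a mapping with a 'kind' key")
    kind = cfg["kind"]
    base_kwargs = {}
    for key, attr in [("mu", "mu"), ("sigma", "sigma"), ("cost", "cost"),
                      ("Rc", "reward_correct"), ("Ri", "reward_incorrect"),
                      ("ti", "iti"), ("delta_t", "delta_t"), ("window", "window")]:
        if key in cfg:
            base_kwargs[attr] = float(cfg[key])
    base = BaseSettings(**base_kwargs)
    if kind == "reward-change":
        return make_reward_change_schedule(float(cfg["R1"]), float(cfg["R2"]), base)
    if kind == "snr-change":
        return make_snr_change_schedule(float(cfg["mu1"]), float(cfg["mu2"]), base)
    if kind == "static":
        return make_static_schedule(base)
    if kind == "tokens":
        return make_tokens_context(
            cfg["speed"], float(cfg["Rc"]), float(cfg["cost"]),
            Ri=float(cfg.get("Ri", -1.0)), base_iti=float(cfg.get("base_iti", 0.5)),
        )
    if kind == "inferred-reward":
        sigma_R = float(cfg.get("sigma_R", 1.0))
        mu_R = math.sqrt(float(cfg["mR"]) * sigma_R**2 / 2.0)
        proc = RewardProcessModel(
            R_high=float(cfg["RH"]), R_low=float(cfg["RL"]), hazard=float(cfg["h"]),
            mu_R=mu_R, sigma_R=sigma_R,
        )
        return make_inferred_reward_context(proc, base)
    raise ValueError(f"unknown context kind {kind!r}")
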