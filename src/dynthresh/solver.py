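"""Reward-rate-optimal decision thresholds by backward induction.

The observer maximises the trial-averaged reward rate

    ρ = (⟨R⟩ - ⟨C(Td)⟩) / (⟨Tt⟩ + ⟨t_i⟩),

which is handled by penalising every action with its time cost scaled by ρ
(average-reward dynamic programming).  At each belief p and time t the value
function is the best of three actions:

    V(p; ρ) = max{ Rc p + Ri (1-p) - ⟨t_i⟩ ρ,           choose s+
                   Rc (1-p) + Ri p - ⟨t_i⟩ ρ,           choose s-
                   ⟨V(p'; ρ) | p⟩ - c δt - ρ δt }       sample again

solved backwards from an artificial horizon Tf (set to five analysis windows
so that the horizon does not contaminate the window of interest).  The
unknown ρ is co-optimised through the consistency requirement
V(p = 1/2, t = 0; ρ*) = 0, a scalar root-finding problem in ρ.

Decision thresholds are the belief levels where the optimal action switches
from sampling to commitment; they may be infinite (waiting optimal for every
belief).  Their time courses fall into a small set of qualitative *motifs*
(wait-then-respond, collapse before a reward drop, non-monotone dips/rises,
...) that this module also classifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .beliefs import BeliefGrid, build_transfer_matrix, likelihood_to_llr
from .contexts import ContextSchedule, TokensState, tokens_likelihood

__all__ = [
    "WAIT",
    "CHOOSE_PLUS",
    "CHOOSE_MINUS",
    "ValueSolution",
    "ThresholdTrace",
    "MotifLabel",
    "MOTIF_LABELS",
    "terminal_value",
    "backward_induction",
    "solve_reward_rate",
    "extract_thresholds",
    "classify_motif",
    "motif_map",
    "solve_inferred_reward",
]

WAIT, CHOOSE_PLUS, CHOOSE_MINUS = 0, 1, 2

MOTIF_LABELS = (
    "wait-then-respond",
    "collapse-to-zero-before-change",
    "nonmonotone-dip",
    "nonmonotone-rise",
    "nonmonotone-mixed",
    "monotone-collapsing",
    "constant-like",
    "stepped",
)


@dataclass(frozen=True)
class MotifLabel:
    """Qualitative class of a threshold time course."""

    label: str

    def __post_init__(self):
        if self.label not in MOTIF_LABELS:
            raise ValueError(f"unknown motif label {self.label!r}")

    def __str__(self):
        return self.label


@dataclass
class ValueSolution:
    """Solved value function, optimal-action map and reward rate for a context.

    For continuous contexts ``value``/``action`` are (n_times, n_grid) arrays
    on ``grid.points``.  For the tokens task they are ragged lists indexed by
    token-movement step, aligned with ``p_by_step``.
    """

    context: ContextSchedule
    rho: float
    times: np.ndarray
    value: object
    action: object
    grid: BeliefGrid | None = None
    p_by_step: list | None = None

    @property
    def value_at_start(self) -> float:
        """V(p = 1/2, t = 0; ρ) — zero at the optimal reward rate."""
        if self.context.kind == "tokens":
            return float(self.value[0][0])
        return float(self.value[0, self.grid.center_index])


def _commit_values(p, Rc, Ri, iti, rho):
    # On a mirror-symmetric grid the choose-minus values are exactly the
    # reversed choose-plus values; computing them that way keeps the value
    # function bitwise symmetric.
    vp = Rc * p + Ri * (1.0 - p) - iti * rho
    vm = vp[::-1]
    return vp, vm


def _commit_max(p, Rc, Ri, iti, rho):
    """Best commitment value and its action, tie toward the side holding p.

    ``p`` must be a full mirror-symmetric grid (p and 1-p both present).
    """
    vp, vm = _commit_values(p, Rc, Ri, iti, rho)
    vc = np.maximum(vp, vm)
    act = np.where(vp > vm, CHOOSE_PLUS,
                   np.where(vm > vp, CHOOSE_MINUS,
                            np.where(p >= 0.5, CHOOSE_PLUS, CHOOSE_MINUS)))
    return vc, act.astype(np.int8)


def terminal_value(grid: BeliefGrid, context: ContextSchedule, rho: float):
    """Value at the horizon, where waiting is impossible: max of the commits."""
    tf = context.t_final
    vc, act = _commit_max(
        grid.points,
        float(context.reward_correct(tf)),
        context.reward_incorrect,
        float(context.iti(tf)),
        rho,
    )
    return vc, act


class _ContinuousEngine:
    """Precomputed quantities for repeated inductions on one Gaussian context."""

    def __init__(self, context: ContextSchedule, grid: BeliefGrid | None = None):
        self.context = context
        self.grid = grid or BeliefGrid()
        self.times = context.times()
        self.Rc = np.asarray(context.reward_correct(self.times), dtype=float)
        self.cost = np.asarray(context.cost(self.times), dtype=float)
        self.iti = np.asarray(context.iti(self.times), dtype=float)
        self.mu = np.asarray(context.mu(self.times), dtype=float)
        from .beliefs import GaussianEvidenceModel

        self.matrices: dict[float, np.ndarray] = {}
        for mu_val in np.unique(self.mu[:-1]):
            model = GaussianEvidenceModel(mu=float(mu_val), sigma=context.sigma, delta_t=context.delta_t)
            self.matrices[float(mu_val)] = build_transfer_matrix(self.grid, model).weights

    def induct(self, rho: float) -> ValueSolution:
        ctx, grid = self.context, self.grid
        n = len(self.times) - 1
        G = len(grid)
        p = grid.points
        dt = ctx.delta_t
        value = np.empty((n + 1, G))
        action = np.empty((n + 1, G), dtype=np.int8)
        value[n], action[n] = terminal_value(grid, ctx, rho)
        for k in range(n - 1, -1, -1):
            M = self.matrices[float(self.mu[k])]
            vw = M @ value[k + 1] - (self.cost[k] + rho) * dt
            vw = 0.5 * (vw + vw[::-1])  # exact mirror symmetry of the wait value
            vc, act = _commit_max(p, self.Rc[k], ctx.reward_incorrect, self.iti[k], rho)
            wait_better = vw > vc
            value[k] = np.where(wait_better, vw, vc)
            action[k] = np.where(wait_better, WAIT, act)
            if not np.all(np.isfinite(value[k])):
                raise FloatingPointError(f"non-finite value at step {k} (rho={rho})")
        return ValueSolution(ctx, rho, self.times, value, action, grid=grid)


_TOKENS_P_TABLE = None


def _tokens_p_table() -> np.ndarray:
    """Cached table P[n, u] = Pr(top wins | u up-moves among first n moves)."""
    global _TOKENS_P_TABLE
    if _TOKENS_P_TABLE is None:
        from .contexts import TOKENS_TOTAL

        N = TOKENS_TOTAL
        tab = np.zeros((N + 1, N + 1))
        for n in range(N + 1):
            for u in range(n + 1):
                tab[n, u] = tokens_likelihood(TokensState(u, n - u, N - n))
        _TOKENS_P_TABLE = tab
    return _TOKENS_P_TABLE


try:  # numba accelerates the tokens backward pass (it sits inside MCMC loops)
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=True)
def _tokens_backward(p_pad, iti, Rc, Ri, c, dt, rho, value, action):  # pragma: no cover
    N = p_pad.shape[0] - 1
    for u in range(N + 1):
        p = p_pad[N, u]
        vp = Rc * p + Ri * (1.0 - p) - iti[N] * rho
        vm = Rc * (1.0 - p) + Ri * p - iti[N] * rho
        if vp > vm or (vp == vm and p >= 0.5):
            value[N, u] = vp
            action[N, u] = 1
        else:
            value[N, u] = vm
            action[N, u] = 2
    for n in range(N - 1, -1, -1):
        pen = (c + rho) * dt
        for u in range(n + 1):
            p = p_pad[n, u]
            vp = Rc * p + Ri * (1.0 - p) - iti[n] * rho
            vm = Rc * (1.0 - p) + Ri * p - iti[n] * rho
            if vp > vm or (vp == vm and p >= 0.5):
                vc, act = vp, 1
            else:
                vc, act = vm, 2
            vw = 0.5 * (value[n + 1, u + 1] + value[n + 1, u]) - pen
            if vw > vc:
                value[n, u] = vw
                action[n, u] = 0
            else:
                value[n, u] = vc
                action[n, u] = act


class _TokensEngine:
    """Backward induction over the 136 reachable token states."""

    def __init__(self, context: ContextSchedule):
        if context.kind != "tokens":
            raise ValueError("tokens engine requires a tokens context")
        self.context = context
        from .contexts import TOKENS_TOTAL

        self.n_total = N = TOKENS_TOTAL
        # p_by_step[n][u] = Pr(top wins | u up-moves among first n)
        self._p_pad = _tokens_p_table()
        self.p_by_step = [self._p_pad[n, : n + 1] for n in range(N + 1)]
        self._iti = np.asarray(context.iti_by_step, dtype=float)
        self.times = np.arange(N + 1) * context.delta_t

    def induct(self, rho: float) -> ValueSolution:
        ctx = self.context
        N = self.n_total
        value = np.zeros((N + 1, N + 1))
        action = np.zeros((N + 1, N + 1), dtype=np.int8)
        _tokens_backward(
            self._p_pad, self._iti,
            float(ctx.reward_correct(0.0)), float(ctx.reward_incorrect),
            float(ctx.cost(0.0)), ctx.delta_t, rho, value, action,
        )
        value_r = [value[n, : n + 1] for n in range(N + 1)]
        action_r = [action[n, : n + 1] for n in range(N + 1)]
        return ValueSolution(ctx, rho, self.times, value_r, action_r, p_by_step=self.p_by_step)


def _make_engine(context: ContextSchedule, grid: BeliefGrid | None = None):
    if context.kind == "tokens":
        return _TokensEngine(context)
    if context.kind == "continuous-gaussian":
        return _ContinuousEngine(context, grid)
    raise ValueError(f"no 1-D engine for context kind {context.kind!r}")


def backward_induction(context: ContextSchedule, rho: float,
                       grid: BeliefGrid | None = None) -> ValueSolution:
    """Solve the value function for a fixed reward rate penalty ρ."""
    return _make_engine(context, grid).induct(rho)


def solve_reward_rate(context: ContextSchedule, grid: BeliefGrid | None = None,
                      tol: float = 1e-9) -> ValueSolution:
    """Co-optimise the reward rate: find ρ* with V(1/2, 0; ρ*) = 0.

    ``g(ρ) = V(1/2, 0; ρ)`` is strictly decreasing (every unit of ρ subtracts
    time-weighted penalties), so a sign-changing bracket exists; it is located
    by expansion and the root found with Brent's method.
    """
    engine = _make_engine(context, grid)
    cache: dict[float, float] = {}

    def g(rho: float) -> float:
        if rho not in cache:
            cache[rho] = engine.induct(rho).value_at_start
        return cache[rho]

    lo, hi = 0.0, max(float(np.max(context.reward_correct(context.times()))), 1.0)
    step = 1.0
    while g(lo) <= 0.0:
        lo -= step
        step *= 2.0
        if lo < -1e4:
            raise RuntimeError("could not bracket the reward rate from below")
    step = 1.0
    while g(hi) >= 0.0:
        hi += step
        step *= 2.0
        if hi > 1e4:
            raise RuntimeError("could not bracket the reward rate from above")
    rho_star = brentq(g, lo, hi, xtol=tol)
    return engine.induct(rho_star)


# ---------------------------------------------------------------------------
# Threshold extraction
# ---------------------------------------------------------------------------

@dataclass
class ThresholdTrace:
    """Per-timestep decision thresholds in likelihood and LLR units.

    Infinite entries (``np.inf`` upper / ``-np.inf`` lower) mark epochs where
    waiting is optimal at every grid belief and the observer never responds.
    """

    times: np.ndarray
    theta_p_upper: np.ndarray
    theta_p_lower: np.ndarray
    window: float
    resolution: float  # grid cell size in likelihood units
    discrete: bool = False  # tokens-style trace (few steps, coarse belief set)
    lead_upper: np.ndarray | None = None  # tokens only: threshold in token-lead units
    policy_p_upper: np.ndarray | None = None  # commit boundary incl. decided states

    def __post_init__(self):
        self.theta_llr_upper = np.where(
            np.isfinite(self.theta_p_upper),
            likelihood_to_llr(np.clip(self.theta_p_upper, 1e-12, 1 - 1e-12)),
            np.inf,
        )
        self.theta_llr_lower = np.where(
            np.isfinite(self.theta_p_lower),
            likelihood_to_llr(np.clip(self.theta_p_lower, 1e-12, 1 - 1e-12)),
            -np.inf,
        )
        if self.policy_p_upper is None:
            self.policy_p_upper = self.theta_p_upper
        self.policy_llr_upper = np.where(
            np.isfinite(self.policy_p_upper),
            likelihood_to_llr(np.clip(self.policy_p_upper, 1e-12, 1 - 1e-12)),
            np.inf,
        )

    def in_window(self) -> "ThresholdTrace":
        """Restrict to the analysis window [0, Tf/5]."""
        keep = self.times <= self.window + 1e-12
        return ThresholdTrace(self.times[keep], self.theta_p_upper[keep],
                              self.theta_p_lower[keep], self.window, self.resolution,
                              self.discrete,
                              None if self.lead_upper is None else self.lead_upper[keep],
                              self.policy_p_upper[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "theta_p_upper": self.theta_p_upper,
                "theta_p_lower": self.theta_p_lower,
                "theta_llr_upper": self.theta_llr_upper,
                "theta_llr_lower": self.theta_llr_lower,
            }
        )

    def interp_llr_upper(self, t):
        """Upper LLR threshold at arbitrary times (previous-step lookup)."""
        idx = np.clip(np.searchsorted(self.times, np.asarray(t), side="right") - 1, 0, len(self.times) - 1)
        return self.theta_llr_upper[idx]


def extract_thresholds(solution: ValueSolution) -> ThresholdTrace:
    """Locate the wait→commit boundaries of the optimal-action map.

    The upper threshold at each timestep is the smallest grid belief where
    choosing s+ is optimal; the lower one the largest where choosing s- is.
    """
    ctx = solution.context
    if ctx.kind == "tokens":
        # Only undecided states (neither target has clinched the majority)
        # carry behavioural information: once U or L reaches 8 the trial is
        # decided and committing is trivially optimal there.
        upper = np.full(len(solution.times), np.inf)
        lower = np.full(len(solution.times), -np.inf)
        lead = np.full(len(solution.times), np.inf)
        policy = np.full(len(solution.times), np.inf)
        for n, (acts, p) in enumerate(zip(solution.action, solution.p_by_step)):
            undecided = np.array([(u < 8) and ((n - u) < 8) for u in range(n + 1)])
            plus = np.flatnonzero((acts == CHOOSE_PLUS) & undecided)
            plus_any = np.flatnonzero(acts == CHOOSE_PLUS)
            if plus.size:
                upper[n] = p[plus[0]]
                lead[n] = 2 * plus[0] - n  # Nt = U - L at the boundary state
                lower[n] = 1.0 - upper[n]  # task symmetry: θ-(t) = 1 - θ+(t)
            if plus_any.size:
                policy[n] = p[plus_any[0]]
        res = 1.0 / 16.0  # coarsest likelihood spacing of the token states
        return ThresholdTrace(solution.times, upper, lower, ctx.window, res,
                              discrete=True, lead_upper=lead, policy_p_upper=policy)
    grid = solution.grid
    acts = solution.action
    n_t = acts.shape[0]
    upper = np.full(n_t, np.inf)
    lower = np.full(n_t, -np.inf)
    for k in range(n_t):
        plus = np.flatnonzero(acts[k] == CHOOSE_PLUS)
        if plus.size:
            upper[k] = grid.points[plus[0]]
            lower[k] = 1.0 - upper[k]  # task symmetry: θ-(t) = 1 - θ+(t)
    res = float(grid.points[1] - grid.points[0])
    return ThresholdTrace(solution.times, upper, lower, ctx.window, res)


# ---------------------------------------------------------------------------
# Motif classification
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, width: int = 3) -> np.ndarray:
    if len(x) < width:
        return x.copy()
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def _significant_extrema(x: np.ndarray, tol: float):
    """Interior extrema of a sequence, ignoring wiggles smaller than tol.

    Returns a list of ('min'|'max') markers in time order, found by tracking
    direction reversals with amplitude at least tol.
    """
    extrema = []
    if len(x) < 3:
        return extrema
    anchor = x[0]
    direction = 0  # +1 rising, -1 falling
    for v in x[1:]:
        if direction >= 0 and v >= anchor + tol:
            if direction == 0:
                direction = 1
            anchor = max(anchor, v)
        elif direction <= 0 and v <= anchor - tol:
            if direction == 0:
                direction = -1
            anchor = min(anchor, v)
        elif direction == 1 and v <= anchor - tol:
            extrema.append("max")
            direction = -1
            anchor = v
        elif direction == -1 and v >= anchor + tol:
            extrema.append("min")
            direction = 1
            anchor = v
        else:
            anchor = anchor if direction == 0 else (max(anchor, v) if direction == 1 else min(anchor, v))
    return extrema


def _classify_discrete(trace: ThresholdTrace) -> MotifLabel:
    """Motif rules for token-step threshold traces.

    Works on the threshold expressed in token-lead units (Nt = U - L), with
    the forced terminal step dropped.  Because the reachable leads alternate
    parity between steps, the raw staircase zig-zags by one token; a width-2
    mean removes this, after which a unit-lead change is a significant event.
    Features: a leading infinite epoch (the observer sits out the early
    movements) and the number of steps at which the threshold *increases*
    (the threshold re-arming as commitment value grows): none → flat or
    collapsing; one → a single re-arming; several → repeated re-arming.
    """
    u = trace.lead_upper[:-1]  # drop forced-choice terminal step
    finite = np.isfinite(u)
    if not finite.any():
        raise ValueError("degenerate trace: thresholds infinite everywhere")
    runs = _runs(~finite)
    has_inf_start = any(a == 0 and (b - a) >= 2 for a, b in runs)
    x = u[finite]
    if x.size >= 2:
        x = 0.5 * (x[1:] + x[:-1])  # pairwise parity smoothing
    tol = 0.9  # just under one token of lead
    n_up = int(np.sum(np.diff(x) > tol)) if x.size >= 2 else 0
    if n_up >= 2:
        return MotifLabel("nonmonotone-mixed")
    if n_up == 1:
        return MotifLabel("nonmonotone-rise")
    if has_inf_start:
        return MotifLabel("wait-then-respond")
    net = x[-1] - x[0] if x.size else 0.0
    if net < -tol:
        return MotifLabel("monotone-collapsing")
    if net > tol:
        return MotifLabel("stepped")
    return MotifLabel("constant-like")


def classify_motif(trace: ThresholdTrace, change_times=(0.5,)) -> MotifLabel:
    """Assign one qualitative motif label to a threshold time course.

    Operational rules (deterministic, applied to the analysis window with the
    forced-choice terminal step dropped; wiggles below three grid cells are
    ignored and the trace is smoothed over three timesteps):

    1. All-infinite trace → degenerate (error).
    2. Trace that touches p = 1/2 (within one grid cell) around a change
       time: if it stays collapsed afterwards → ``collapse-to-zero-before-
       change`` (every trial responds while the pre-change context holds);
       if it rebounds above 1/2 after the change → ``nonmonotone-mixed``
       (a collapse episode combined with a post-change recovery).
    3. Trace with an infinite epoch (≥ 2 consecutive all-wait steps): if the
       finite part before the epoch rises significantly, the threshold
       re-arms before the change → ``nonmonotone-rise``; otherwise the
       observer simply sits out the early context → ``wait-then-respond``.
    4. Finite trace: classify by significant interior extrema — one minimum
       → ``nonmonotone-dip``; one maximum → ``nonmonotone-rise``; several →
       ``nonmonotone-mixed``; none → ``monotone-collapsing`` /
       ``constant-like`` / ``stepped`` by net slope.

    Token-task traces use step-count analogues of the same features (see
    :func:`_classify_discrete`).
    """
    tw = trace.in_window()
    if tw.discrete:
        return _classify_discrete(tw)
    t = tw.times
    up = tw.theta_p_upper
    if not np.isfinite(up).any():
        raise ValueError("degenerate trace: thresholds infinite everywhere in the window")
    cell = tw.resolution
    tol = 3.0 * cell
    # drop the final timestep: at the solver horizon commitment is forced
    upw = up[:-1] if len(t) > 4 else up
    tvec = t[: len(upw)]
    finite = np.isfinite(upw)
    x = _smooth(upw[finite]) if finite.sum() >= 3 else upw[finite]

    changes = [c for c in change_times if 0.0 < c < tw.window]
    c0 = changes[0] if changes else None

    # feature: does the trace *descend* to p = 1/2 around the change?  (a
    # trace that starts at 1/2 -- immediate responding -- is not a collapse)
    xf = upw[finite]
    touched = xf <= 0.5 + cell
    starts_collapsed = touched.size and touched[0]
    if touched.any() and not starts_collapsed and c0 is not None:
        after = finite & (tvec >= c0)
        post = upw[after]
        post = post[np.isfinite(post)]
        if post.size:
            if np.mean(post <= 0.5 + tol) >= 0.5:
                return MotifLabel("collapse-to-zero-before-change")
            return MotifLabel("nonmonotone-mixed")

    runs = _runs(~finite)
    inf_epochs = [(a, b) for a, b in runs if (b - a) >= 2]
    if inf_epochs:
        a0 = inf_epochs[0][0]
        pre = upw[:a0][np.isfinite(upw[:a0])]
        pre_rise = pre.size >= 2 and (np.max(pre) - pre[0]) > tol
        if pre_rise:
            return MotifLabel("nonmonotone-rise")
        return MotifLabel("wait-then-respond")

    extrema = _significant_extrema(x, tol)
    if not extrema:
        net = x[-1] - x[0] if x.size else 0.0
        if net < -tol:
            return MotifLabel("monotone-collapsing")
        if net > tol:
            return MotifLabel("stepped")
        return MotifLabel("constant-like")
    if len(extrema) == 1:
        return MotifLabel("nonmonotone-dip" if extrema[0] == "min" else "nonmonotone-rise")
    return MotifLabel("nonmonotone-mixed")


def _runs(mask: np.ndarray):
    """(start, end) index pairs of True runs in a boolean array."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


# ---------------------------------------------------------------------------
# Motif maps
# ---------------------------------------------------------------------------

def motif_map(param1, param2, task_kind: str, grid: BeliefGrid | None = None,
              progress: bool = False) -> pd.DataFrame:
    """Label the threshold motif over a 2-D parameter grid.

    ``task_kind`` selects the context family and the meaning of the axes:

    * ``"reward-change"``: (R1, R2) pre/post-change rewards;
    * ``"snr-change"``: (m1, m2) pre/post-change evidence quality;
    * ``"tokens-slow"`` / ``"tokens-fast"``: (Rc, c) reward and cost.

    Cells where the solver fails are labelled ``"failed"``; the sweep
    continues.
    """
    from .contexts import make_reward_change_schedule, make_snr_change_schedule, make_tokens_context

    rows = []
    for a in param1:
        for b in param2:
            try:
                if task_kind == "reward-change":
                    ctx = make_reward_change_schedule(a, b)
                elif task_kind == "snr-change":
                    import math

                    ctx = make_snr_change_schedule(math.sqrt(a / 2.0), math.sqrt(b / 2.0))
                elif task_kind in ("tokens-slow", "tokens-fast"):
                    ctx = make_tokens_context(task_kind.split("-")[1], Rc=a, cost=b)
                else:
                    raise ValueError(f"unknown task kind {task_kind!r}")
                sol = solve_reward_rate(ctx, grid=grid)
                label = str(classify_motif(extract_thresholds(sol)))
                rho = sol.rho
            except Exception:
                label, rho = "failed", np.nan
            rows.append({"param1": a, "param2": b, "label": label, "rho": rho})
            if progress:
                print(f"{task_kind}: ({a:g}, {b:g}) -> {rows[-1]['label']}", flush=True)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Inferred reward-change (2-D belief) solver
# ---------------------------------------------------------------------------

@dataclass
class InferredRewardSolution:
    """Value and action over the joint (state belief p, reward belief q) grid."""

    context: ContextSchedule
    rho: float
    times: np.ndarray
    value0: np.ndarray  # V(p, q) at t = 0
    action: np.ndarray  # (n_times, n_p, n_q) int8
    p_grid: BeliefGrid
    q_grid: BeliefGrid

    @property
    def value_at_start(self) -> float:
        return float(self.value0[self.p_grid.center_index, self.q_grid.center_index])


def _q_transfer_matrix(q_grid: BeliefGrid, proc, delta_t: float) -> np.ndarray:
    """One-Euler-step kernel for the reward belief q under the sinh-DDM.

    From reward-LLR y_R the step is
    ``y_R' = y_R + x m_R δt - 2h sinh(y_R) δt + √(2 m_R δt) Z`` with the
    telegraph sign x = +1 with probability q; rows mix the two branches with
    weights (q, 1-q) and are renormalised on the grid.
    """
    y = q_grid.llr_points
    m_R, h = proc.m_R, proc.hazard
    if m_R == 0.0:
        return np.eye(len(q_grid))
    sd = np.sqrt(2.0 * m_R * delta_t)
    drift = -2.0 * h * np.sinh(np.clip(y, -30, 30)) * delta_t
    w = q_grid.trapezoid_weights()
    # density in q-space: change of variables dy/dq = 1/(q(1-q))
    jac = 1.0 / (q_grid.points * (1.0 - q_grid.points))
    centers_p = y + m_R * delta_t + drift
    centers_m = y - m_R * delta_t + drift
    z_p = (y[None, :] - centers_p[:, None]) / sd
    z_m = (y[None, :] - centers_m[:, None]) / sd
    gauss = lambda z: np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * sd)
    q = q_grid.points[:, None]
    dens = q * gauss(z_p) + (1.0 - q) * gauss(z_m)
    W = dens * (jac * w)[None, :]
    total = W.sum(axis=1, keepdims=True)
    # rows whose Euler step lands far outside the grid (strong sinh drift at
    # extreme beliefs) underflow; send them to the nearest grid point of the
    # mixture-mean centre instead
    dead = total[:, 0] <= 1e-300
    if dead.any():
        centers = q[:, 0] * centers_p + (1.0 - q[:, 0]) * centers_m
        nearest = np.abs(y[None, :] - np.clip(centers, y[0], y[-1])[:, None]).argmin(axis=1)
        W[dead] = 0.0
        W[dead, nearest[dead]] = 1.0
        total = W.sum(axis=1, keepdims=True)
    W /= total
    return W


def solve_inferred_reward(context: ContextSchedule, n_p: int = 201, n_q: int = 101,
                          rho: float | None = None, tol: float = 1e-9) -> InferredRewardSolution:
    """Backward induction on the joint (p, q) belief for the inferred-reward task.

    Commitment values use the expected reward ``R_H q + R_L (1-q)``; the p and
    q beliefs evolve independently, so the expectation over the next joint
    belief factorises into two kernel contractions per step.  If ``rho`` is
    None the reward rate is co-optimised as in :func:`solve_reward_rate`.
    """
    if context.kind != "inferred-reward":
        raise ValueError("context must be of kind 'inferred-reward'")
    proc = context.reward_process
    p_grid = BeliefGrid(n_points=n_p)
    q_grid = BeliefGrid(n_points=n_q)
    from .beliefs import GaussianEvidenceModel

    model = GaussianEvidenceModel(mu=float(context.mu(0.0)), sigma=context.sigma, delta_t=context.delta_t)
    Mp = build_transfer_matrix(p_grid, model).weights
    Mq = _q_transfer_matrix(q_grid, proc, context.delta_t)
    p = p_grid.points[:, None]
    q = q_grid.points[None, :]
    exp_R = proc.expected_reward(q)
    iti = float(context.iti(0.0))
    c = float(context.cost(0.0))
    Ri = context.reward_incorrect
    dt = context.delta_t
    n = context.n_steps
    times = context.times()

    def induct(rho_val: float):
        vp = exp_R * p + Ri * (1.0 - p) - iti * rho_val
        vm = exp_R * (1.0 - p) + Ri * p - iti * rho_val
        commit = np.maximum(vp, vm)
        commit_act = np.where(vp >= vm, CHOOSE_PLUS, CHOOSE_MINUS).astype(np.int8)
        action = np.empty((n + 1, n_p, n_q), dtype=np.int8)
        V = commit.copy()
        action[n] = commit_act
        for k in range(n - 1, -1, -1):
            vw = Mp @ V @ Mq.T - (c + rho_val) * dt
            wait_better = vw > commit
            V = np.where(wait_better, vw, commit)
            action[k] = np.where(wait_better, WAIT, commit_act)
        return V, action

    if rho is None:
        cache = {}

        def g(r):
            if r not in cache:
                V, _ = induct(r)
                cache[r] = float(V[p_grid.center_index, q_grid.center_index])
            return cache[r]

        lo, hi = 0.0, max(proc.R_high / iti, 1.0)
        step = 1.0
        while g(lo) <= 0.0:
            lo -= step
            step *= 2.0
            if lo < -1e4:
                raise RuntimeError("could not bracket the reward rate from below")
        step = 1.0
        while g(hi) >= 0.0:
            hi += step
            step *= 2.0
            if hi > 1e4:
                raise RuntimeError("could not bracket the reward rate from above")
        rho = brentq(g, lo, hi, xtol=tol)
    V0, action = induct(rho)
    return InferredRewardSolution(context, rho, times, V0, action, p_grid, q_grid)
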