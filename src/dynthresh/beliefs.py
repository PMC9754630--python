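"""Belief (log-likelihood-ratio) representation for Gaussian 2AFC evidence.

The ideal observer for a two-alternative task with latent state ``s ∈ {s+, s-}``
and Gaussian observations ``ξ | s± ~ N(±μ δt, σ² δt)`` tracks the log-likelihood
ratio (LLR) ``y = ln Pr(s+|ξ_1:n) / Pr(s-|ξ_1:n)``, or equivalently the state
likelihood ``p = 1/(1+e^{-y})``.  Evidence quality is summarised by the
signal-to-noise ratio ``m = 2μ²/σ²`` (units 1/time).

This module provides:

* :class:`BeliefGrid` -- a symmetric discretisation of ``p ∈ (0, 1)`` used as
  the substrate for dynamic programming;
* :class:`GaussianEvidenceModel` -- the evidence-generating process;
* the one-step likelihood transfer density ``f_p(p' | p)`` and its discretised
  :class:`TransferMatrix`;
* an Euler--Maruyama simulator for (optionally sensory-noise-corrupted) belief
  paths ``dỹ = ±m dt + √(2m) dW + σ_y dW'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeliefGrid",
    "GaussianEvidenceModel",
    "TransferMatrix",
    "likelihood_to_llr",
    "llr_to_likelihood",
    "convert_belief",
    "llr_update",
    "gaussian_transfer_density",
    "build_transfer_matrix",
    "simulate_belief_path",
]


def likelihood_to_llr(p):
    """Map a state likelihood ``p ∈ (0,1)`` to the LLR ``y = ln(p/(1-p))``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("state likelihood must lie in the open interval (0, 1)")
    # log(p) - log(1-p): antisymmetric under p -> 1-p up to the rounding of
    # the complement itself
    return np.log(p) - np.log(1.0 - p)


def llr_to_likelihood(y):
    """Map an LLR ``y`` to the state likelihood ``p = 1/(1+e^{-y})``."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("LLR must be finite")
    # expit, written out to avoid importing scipy for one line
    return 0.5 * (1.0 + np.tanh(0.5 * y))


def convert_belief(value, direction: str):
    """Convert between state-likelihood and LLR representations of belief.

    Parameters
    ----------
    value : array_like
        Likelihood(s) in (0,1) if ``direction == "to_llr"``, finite LLR(s) if
        ``direction == "to_likelihood"``.
    direction : {"to_llr", "to_likelihood"}
    """
    if direction == "to_llr":
        return likelihood_to_llr(value)
    if direction == "to_likelihood":
        return llr_to_likelihood(value)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class GaussianEvidenceModel:
    """Gaussian evidence source ``f±(ξ) = N(±μ, σ²)`` observed every ``δt``.

    Parameters
    ----------
    mu : float
        Drift magnitude μ (belief units per unit time).
    sigma : float
        Observation noise σ (> 0).
    delta_t : float
        Observation interval δt (> 0).
    """

    mu: float
    sigma: float
    delta_t: float = 0.01

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def m(self) -> float:
        """Evidence quality (SNR) ``m = 2μ²/σ²``, units 1/time."""
        return 2.0 * self.mu**2 / self.sigma**2


@dataclass(frozen=True)
class BeliefGrid:
    """Symmetric discretisation of the state-likelihood space ``p ∈ (0, 1)``.

    Grid points are uniformly spaced on ``[ε, 1-ε]`` with an odd count so that
    p = 1/2 is an exact grid point and the grid maps onto itself under the
    mirror reflection ``p ↦ 1-p``.
    """

    n_points: int = 501
    epsilon: float = 1e-4
    points: np.ndarray = field(init=False, repr=False, compare=False)
    llr_points: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("belief grid needs at least 3 points")
        if self.n_points % 2 == 0:
            raise ValueError("belief grid size must be odd so that p=1/2 is a point")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must be in (0, 0.5)")
        pts = np.linspace(self.epsilon, 1.0 - self.epsilon, self.n_points)
        # enforce exact symmetry against accumulated floating error
        pts = 0.5 * (pts + (1.0 - pts[::-1]))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "llr_points", likelihood_to_llr(pts))

    def __len__(self) -> int:
        return self.n_points

    @property
    def center_index(self) -> int:
        """Index of the p = 1/2 grid point."""
        return self.n_points // 2

    def mirror(self, index):
        """Index of the point reflected through p = 1/2."""
        return self.n_points - 1 - np.asarray(index)

    def trapezoid_weights(self) -> np.ndarray:
        w = np.empty(self.n_points)
        dp = np.diff(self.points)
        w[0] = 0.5 * dp[0]
        w[-1] = 0.5 * dp[-1]
        w[1:-1] = 0.5 * (dp[:-1] + dp[1:])
        return w


def llr_update(y_prev, xi, model: GaussianEvidenceModel):
    """One-step LLR update for a Gaussian observation.

    The log-ratio of the two Gaussian densities ``N(±μδt, σ²δt)`` at ξ is
    ``2 ξ μ / σ²``, so the posterior LLR is additive in the observations:
    ``y_n = y_{n-1} + 2 ξ_n μ / σ²``.
    """
    return np.asarray(y_prev, dtype=float) + 2.0 * np.asarray(xi, dtype=float) * model.mu / model.sigma**2


def gaussian_transfer_density(p_next, p_curr, model: GaussianEvidenceModel):
    """One-step likelihood transfer density ``f_p(p_{n+1} | p_n)``.

    The observation that carries the belief from ``p_n`` to ``p_{n+1}`` is
    recovered by inverting the Bayesian update,

    ``ξ = (σ²/2μ) · ln[ (p_n - 1) p_{n+1} / (p_n (p_{n+1} - 1)) ]``,

    and the observation itself is drawn from the two-component mixture
    ``p_n N(+μδt, σ²δt) + (1-p_n) N(-μδt, σ²δt)`` (the observer does not know
    the state, so it is marginalised with the current belief as weight).  A
    change of variables with ``dξ/dp' = σ² / (2μ p'(1-p'))`` gives the density
    over the next state likelihood.  Degenerate for μ = 0, where the belief
    does not move (a Dirac mass handled by the matrix builder, not here).
    """
    p_next = np.asarray(p_next, dtype=float)
    p_curr = np.asarray(p_curr, dtype=float)
    if np.any((p_next <= 0) | (p_next >= 1)) or np.any((p_curr <= 0) | (p_curr >= 1)):
        raise ValueError("likelihoods must lie strictly inside (0, 1)")
    mu, sigma, dt = model.mu, model.sigma, model.delta_t
    if mu == 0.0:
        raise ValueError("transfer density is a point mass for mu=0; handled upstream")
    # ξ as a function of (p, p'): difference of LLRs scaled by σ²/2μ
    dy = likelihood_to_llr(p_next) - likelihood_to_llr(p_curr)
    xi = sigma**2 / (2.0 * mu) * dy
    norm = 1.0 / np.sqrt(2.0 * np.pi * dt) / sigma
    gp = norm * np.exp(-0.5 * (xi - mu * dt) ** 2 / (sigma**2 * dt))
    gm = norm * np.exp(-0.5 * (xi + mu * dt) ** 2 / (sigma**2 * dt))
    jac = sigma**2 / (2.0 * np.abs(mu) * p_next * (1.0 - p_next))
    return jac * (p_curr * gp + (1.0 - p_curr) * gm)


@dataclass(frozen=True)
class TransferMatrix:
    """Row-stochastic one-step transition kernel on a :class:`BeliefGrid`.

    ``weights[i, j]`` is the probability of moving from grid point i to grid
    point j in one observation interval.
    """

    grid: BeliefGrid
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.grid), len(self.grid)):
            raise ValueError("weights shape must match the grid")
        if np.any(w < 0):
            raise ValueError("transfer weights must be nonnegative")
        rs = w.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > 1e-6):
            raise ValueError("transfer rows must sum to 1 within 1e-6")

    def expected_next(self, values: np.ndarray) -> np.ndarray:
        """E[v(p_{n+1}) | p_n] for each grid point (one matrix-vector product)."""
        return self.weights @ values


def build_transfer_matrix(grid: BeliefGrid, model: GaussianEvidenceModel) -> TransferMatrix:
    """Discretise the likelihood transfer density on the grid.

    Rows are the transfer density sampled at the destination grid points,
    weighted by trapezoid quadrature weights and renormalised to sum to one.
    For uninformative evidence (μ = 0) the belief is frozen: the matrix is the
    identity.
    """
    if len(grid) < 3:
        raise ValueError("degenerate grid")
    n = len(grid)
    if model.mu == 0.0:
        return TransferMatrix(grid, np.eye(n))
    w = grid.trapezoid_weights()
    dens = gaussian_transfer_density(grid.points[None, :], grid.points[:, None], model)
    weights = dens * w[None, :]
    weights /= weights.sum(axis=1, keepdims=True)
    # enforce exact mirror symmetry w(i→j) = w(mirror(i)→mirror(j))
    weights = 0.5 * (weights + weights[::-1, ::-1])
    return TransferMatrix(grid, weights)


def simulate_belief_path(
    state: int,
    model: GaussianEvidenceModel,
    sigma_y: float = 0.0,
    horizon: float = 1.0,
    rng: np.random.Generator | int | None = None,
    n_paths: int = 1,
):
    """Euler--Maruyama sample paths of the (noisy) LLR SDE.

    ``dỹ = ±m dt + √(2m) dW + σ_y dW'`` with the drift sign set by the latent
    state.  Returns ``(t, y)`` with ``y`` of shape ``(n_paths, len(t))``;
    paths start at y = 0.

    Parameters
    ----------
    state : {+1, -1}
        Latent state; sets the drift sign.
    sigma_y : float
        Sensory-noise strength σ_y ≥ 0 (diffusion added on top of the
        evidence-driven fluctuations).
    """
    if state not in (+1, -1):
        raise ValueError("state must be +1 or -1")
    if sigma_y < 0:
        raise ValueError("sigma_y must be nonnegative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(rng)
    dt = model.delta_t
    n_steps = int(round(horizon / dt))
    m = model.m
    t = np.arange(n_steps + 1) * dt
    incr = state * m * dt + np.sqrt(2.0 * m * dt) * rng.standard_normal((n_paths, n_steps))
    if sigma_y > 0:
        incr = incr + sigma_y * np.sqrt(dt) * rng.standard_normal((n_paths, n_steps))
    y = np.zeros((n_paths, n_steps + 1))
    np.cumsum(incr, axis=1, out=y[:, 1:])
    return t, y
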