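"""Model fitting and comparison for tokens-task response times.

The data for one subject are trials of 15 Bernoulli(1/2) token movements with
one binned response time each (bins 0..15, one per movement).  Models are fit
to the *marginal* response-time distribution: the likelihood of a parameter
vector is the product over trials of the model's probability of the observed
response bin, with the model distribution estimated by Monte-Carlo simulation
(floored at 1e-6 and renormalised so the log-likelihood stays finite).

Posteriors are sampled with a Metropolis chain using a Gaussian random-walk
proposal under bounded flat priors.  A fixed simulation seed per chain keeps
the pseudo-likelihood surface deterministic, so proposals compete on
parameters rather than on Monte-Carlo jitter.

Model comparison uses corrected AIC,

    AICc = 2k - 2 ln L̂ + (2k² + 2k)/(n - k - 1),

the mean trial-by-trial response-time RMSE at the MAP parameters, and the KL
divergence between data and model response distributions over the 16 bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import TOKEN_INTERVAL, TOKENS_TOTAL, make_tokens_context
from .simulate import ConstParams, NBParams, UGMParams, simulate_tokens_trials, tokens_sim_arrays
from .solver import extract_thresholds, solve_reward_rate

__all__ = [
    "PARAM_BOUNDS",
    "PARAM_NAMES",
    "SubjectDataset",
    "PosteriorSamples",
    "FitResult",
    "params_to_vector",
    "vector_to_params",
    "predict_rt_distribution",
    "log_likelihood",
    "mcmc_sample",
    "aicc",
    "trial_rmse",
    "kl_divergence",
    "select_model",
    "fit_subject",
    "dataset_to_frame",
    "frame_to_datasets",
]

N_BINS = TOKENS_TOTAL + 1
RT_FLOOR = 1e-6

#: flat-prior bounds per parameter (chosen to contain all threshold regimes)
PARAM_BOUNDS = {
    "Rc": (1e-6, 50.0),
    "c": (0.0, 10.0),
    "sigma_y": (0.0, 5.0),
    "sigma_mn": (0.0, 0.25),
    "theta0": (1e-6, 10.0),
    "a": (1e-6, 10.0),
    "tau": (0.01, 2.0),
}

PARAM_NAMES = {
    "nb": ("Rc", "c", "sigma_y", "sigma_mn"),
    "const": ("theta0", "sigma_y", "sigma_mn"),
    "ugm": ("theta0", "a", "sigma_y", "tau", "sigma_mn"),
}

#: diagonal random-walk proposal SDs, scaled for ~25% acceptance on synthetic
#: tuning subjects
PROPOSAL_SCALES = {
    "nb": np.array([0.25, 0.06, 0.1, 0.008]),
    "const": np.array([0.07, 0.1, 0.008]),
    "ugm": np.array([0.03, 0.08, 0.06, 0.02, 0.006]),
}

_PARAM_CLASSES = {"nb": NBParams, "const": ConstParams, "ugm": UGMParams}


def params_to_vector(params) -> np.ndarray:
    kind = model_kind_of(params)
    return np.array([getattr(params, name) for name in PARAM_NAMES[kind]])


def vector_to_params(vec, model_kind: str):
    names = PARAM_NAMES[model_kind]
    if len(vec) != len(names):
        raise ValueError(f"{model_kind} expects {len(names)} parameters")
    return _PARAM_CLASSES[model_kind](**dict(zip(names, vec)))


def model_kind_of(params) -> str:
    for kind, cls in _PARAM_CLASSES.items():
        if isinstance(params, cls):
            return kind
    raise TypeError(f"unknown parameter type {type(params)!r}")


def n_free_parameters(model_kind: str) -> int:
    return len(PARAM_NAMES[model_kind])


def in_bounds(vec, model_kind: str) -> bool:
    for v, name in zip(vec, PARAM_NAMES[model_kind]):
        lo, hi = PARAM_BOUNDS[name]
        if not (lo <= v <= hi):
            return False
    return True


@dataclass
class SubjectDataset:
    """Trials of one subject: token sequences plus binned response times."""

    sequences: np.ndarray  # (n_trials, 15) of ±1 moves (+1 = up)
    rt_bins: np.ndarray    # (n_trials,) ints in 0..15
    speed: str             # {"slow", "fast"}
    subject_id: str = "s0"

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=int)
        self.rt_bins = np.asarray(self.rt_bins, dtype=int)
        if self.sequences.ndim != 2 or self.sequences.shape[1] != TOKENS_TOTAL:
            raise ValueError(f"sequences must be (n, {TOKENS_TOTAL})")
        if len(self.rt_bins) != len(self.sequences):
            raise ValueError("one response bin per trial required")
        if np.any((self.rt_bins < 0) | (self.rt_bins > TOKENS_TOTAL)):
            raise ValueError("response bins must lie in 0..15")
        if not np.all(np.isin(self.sequences, (-1, 1))):
            raise ValueError("token moves must be ±1")
        if self.speed not in ("slow", "fast"):
            raise ValueError("speed must be 'slow' or 'fast'")

    @property
    def n_trials(self) -> int:
        return len(self.rt_bins)

    def rt_distribution(self) -> np.ndarray:
        """Empirical response-bin distribution (sums to 1)."""
        counts = np.bincount(self.rt_bins, minlength=N_BINS).astype(float)
        return counts / counts.sum()


@dataclass
class PosteriorSamples:
    """Metropolis chain output."""

    samples: np.ndarray       # (chain_length, k)
    log_posts: np.ndarray     # (chain_length,)
    model_kind: str
    acceptance_rate: float
    seed: int
    burn_in: int

    def retained(self) -> np.ndarray:
        return self.samples[self.burn_in:]

    @property
    def map_vector(self) -> np.ndarray:
        idx = self.burn_in + int(np.argmax(self.log_posts[self.burn_in:]))
        return self.samples[idx]


@dataclass
class FitResult:
    """Summary of one model fit to one subject."""

    model_kind: str
    map_params: object
    log_like_hat: float
    k: int
    n: int
    aicc: float
    mean_rmse: float
    kl: float
    acceptance_rate: float


def _nb_thresholds(Rc: float, c: float, speed: str, Ri: float = -1.0):
    ctx = make_tokens_context(speed, Rc=Rc, cost=c, Ri=Ri)
    return ctx, extract_thresholds(solve_reward_rate(ctx))


def predict_rt_distribution(params, speed: str, n_sim: int = 2000,
                            rng: np.random.Generator | int | None = None,
                            Ri: float = -1.0) -> np.ndarray:
    """Monte-Carlo response-bin distribution of a model (length 16, sums to 1)."""
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000 for a usable histogram")
    if speed not in ("slow", "fast"):
        raise ValueError("speed must be 'slow' or 'fast'")
    rng = np.random.default_rng(rng)
    seqs = rng.choice([-1, 1], size=(n_sim, TOKENS_TOTAL))
    ctx = make_tokens_context(speed, Rc=1.0, cost=0.0, Ri=Ri)
    thresholds = None
    if isinstance(params, NBParams):
        ctx, thresholds = _nb_thresholds(params.Rc, params.c, speed, Ri)
    cols = tokens_sim_arrays(params, seqs, ctx, rng=rng, thresholds=thresholds)
    counts = np.bincount(cols["rt_bin"], minlength=N_BINS).astype(float)
    dist = counts / counts.sum()
    dist = np.maximum(dist, RT_FLOOR)
    return dist / dist.sum()


def log_likelihood(params, data: SubjectDataset, n_sim: int = 2000,
                   rng: np.random.Generator | int | None = None) -> float:
    """Marginal response-time log-likelihood Σ_trials ln RTM(bin)."""
    if data.n_trials == 0:
        raise ValueError("empty dataset")
    rtm = predict_rt_distribution(params, data.speed, n_sim=n_sim, rng=rng)
    counts = np.bincount(data.rt_bins, minlength=N_BINS)
    return float(np.sum(counts * np.log(rtm)))


def mcmc_sample(data: SubjectDataset, model_kind: str, chain_length: int = 10_000,
                proposal_scales: np.ndarray | None = None, n_sim: int = 2000,
                seed: int = 0, init: np.ndarray | None = None,
                burn_in_fraction: float = 0.1) -> PosteriorSamples:
    """Metropolis sampling of the parameter posterior under bounded flat priors.

    A Gaussian random-walk proposal with diagonal covariance is used; the
    simulated likelihood inside one chain reuses a fixed simulation seed
    (common random numbers), making the target deterministic.  Proposals
    outside the prior bounds are rejected outright.
    """
    if model_kind not in PARAM_NAMES:
        raise ValueError(f"unknown model kind {model_kind!r}")
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(2**31))
    scales = PROPOSAL_SCALES[model_kind] if proposal_scales is None else np.asarray(proposal_scales)

    def logp(vec):
        if not in_bounds(vec, model_kind):
            return -np.inf
        params = vector_to_params(vec, model_kind)
        return log_likelihood(params, data, n_sim=n_sim, rng=np.random.default_rng(sim_seed))

    if init is None:
        init = _default_init(model_kind)
    x = np.asarray(init, dtype=float)
    lp = logp(x)
    if not np.isfinite(lp):
        raise ValueError("chain initialisation has zero posterior mass")
    k = len(x)
    samples = np.empty((chain_length, k))
    log_posts = np.empty(chain_length)
    n_accept = 0
    for i in range(chain_length):
        prop = x + scales * rng.standard_normal(k)
        lp_prop = logp(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_accept += 1
        elif i == 499 and n_accept == 0:
            # a chain that never moves in its first 500 steps signals a
            # mis-scaled proposal, not a sticky mode
            raise RuntimeError(
                "no accepted proposal in the first 500 steps; "
                "proposal scale likely too large"
            )
        samples[i] = x
        log_posts[i] = lp
    return PosteriorSamples(
        samples=samples,
        log_posts=log_posts,
        model_kind=model_kind,
        acceptance_rate=n_accept / chain_length,
        seed=seed,
        burn_in=int(burn_in_fraction * chain_length),
    )


def _default_init(model_kind: str) -> np.ndarray:
    # mid-regime starting points; flat priors make the exact choice a matter
    # of burn-in only
    return {
        "nb": np.array([2.0, 0.5, 0.5, 0.05]),
        "const": np.array([1.5, 0.5, 0.05]),
        "ugm": np.array([0.3, 1.0, 0.5, 0.2, 0.05]),
    }[model_kind]


def aicc(log_like_hat: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return 2.0 * k - 2.0 * log_like_hat + (2.0 * k**2 + 2.0 * k) / (n - k - 1)


def trial_rmse(map_params, data: SubjectDataset, n_rep: int = 20,
               rng: np.random.Generator | int | None = None) -> float:
    """Mean RMSE between observed and predicted trial-by-trial response times.

    The prediction for each trial is the mean response time over ``n_rep``
    noisy replays of the model on that trial's token sequence; times are in
    seconds.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be positive")
    rng = np.random.default_rng(rng)
    ctx = make_tokens_context(data.speed, Rc=1.0, cost=0.0)
    thresholds = None
    if isinstance(map_params, NBParams):
        ctx, thresholds = _nb_thresholds(map_params.Rc, map_params.c, data.speed)
    seqs = np.repeat(data.sequences, n_rep, axis=0)
    df = simulate_tokens_trials(map_params, seqs, ctx, rng=rng, thresholds=thresholds)
    pred = df["rt_observed"].to_numpy().reshape(data.n_trials, n_rep).mean(axis=1)
    obs = data.rt_bins * TOKEN_INTERVAL
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def kl_divergence(rtd: np.ndarray, rtm: np.ndarray) -> float:
    """KL divergence Σ_i RTD(i) ln(RTD(i)/RTM(i)) over the 16 response bins."""
    rtd = np.asarray(rtd, dtype=float)
    rtm = np.asarray(rtm, dtype=float)
    if rtd.shape != (N_BINS,) or rtm.shape != (N_BINS,):
        raise ValueError(f"both distributions must have length {N_BINS}")
    if np.any(rtd < 0) or np.any(rtm < 0):
        raise ValueError("probabilities must be nonnegative")
    rtm = np.maximum(rtm, RT_FLOOR)
    rtm = rtm / rtm.sum()
    mask = rtd > 0
    return float(np.sum(rtd[mask] * np.log(rtd[mask] / rtm[mask])))


def fit_subject(data: SubjectDataset, model_kind: str, chain_length: int = 10_000,
                n_sim: int = 2000, seed: int = 0, n_rep_rmse: int = 20) -> FitResult:
    """Full pipeline for one (subject, model) pair: MCMC → MAP → metrics."""
    post = mcmc_sample(data, model_kind, chain_length=chain_length, n_sim=n_sim, seed=seed)
    map_vec = post.map_vector
    map_params = vector_to_params(map_vec, model_kind)
    rng = np.random.default_rng(seed + 1)
    ll_hat = log_likelihood(map_params, data, n_sim=n_sim, rng=rng)
    k = n_free_parameters(model_kind)
    result = FitResult(
        model_kind=model_kind,
        map_params=map_params,
        log_like_hat=ll_hat,
        k=k,
        n=data.n_trials,
        aicc=aicc(ll_hat, k, data.n_trials),
        mean_rmse=trial_rmse(map_params, data, n_rep=n_rep_rmse, rng=rng),
        kl=kl_divergence(data.rt_distribution(),
                         predict_rt_distribution(map_params, data.speed, n_sim=n_sim, rng=rng)),
        acceptance_rate=post.acceptance_rate,
    )
    return result


def select_model(fits: dict[str, FitResult], criterion: str = "aicc",
                 tie_tol: float = 1e-9):
    """Winning model by AICc or mean RMSE; ties are reported, not broken.

    Returns ``(winner, tied)`` where ``tied`` lists all models within
    ``tie_tol`` of the best criterion value (including the winner when a tie
    exists).
    """
    if criterion not in ("aicc", "rmse"):
        raise ValueError("criterion must be 'aicc' or 'rmse'")
    if not fits:
        raise ValueError("no fits supplied")
    key = (lambda f: f.aicc) if criterion == "aicc" else (lambda f: f.mean_rmse)
    items = sorted(fits.items(), key=lambda kv: (key(kv[1]), kv[0]))
    best_kind, best_fit = items[0]
    tied = [kind for kind, f in items if abs(key(f) - key(best_fit)) <= tie_tol]
    return best_kind, (tied if len(tied) > 1 else [])


# ---------------------------------------------------------------------------
# Dataset serialisation (CSV dialect shared with the synthetic generator)
# ---------------------------------------------------------------------------

def dataset_to_frame(data: SubjectDataset) -> pd.DataFrame:
    """Flatten a dataset to the interchange CSV layout."""
    cols = {
        "subject_id": data.subject_id,
        "speed": data.speed,
        "trial": np.arange(data.n_trials),
    }
    for j in range(TOKENS_TOTAL):
        cols[f"move_{j + 1}"] = np.where(data.sequences[:, j] == 1, "U", "D")
    cols["rt_bin"] = data.rt_bins
    return pd.DataFrame(cols)


def frame_to_datasets(frame: pd.DataFrame) -> list[SubjectDataset]:
    """Rebuild per-subject datasets from the interchange layout."""
    move_cols = [f"move_{j + 1}" for j in range(TOKENS_TOTAL)]
    out = []
    for (sid, speed), grp in frame.groupby(["subject_id", "speed"], sort=True):
        seqs = np.where(grp[move_cols].to_numpy() == "U", 1, -1)
        out.append(SubjectDataset(seqs, grp["rt_bin"].to_numpy(), str(speed), str(sid)))
    return out


def load_subject_csv(path: str | Path) -> list[SubjectDataset]:
    return frame_to_datasets(pd.read_csv(path))


def save_subject_csv(datasets, path: str | Path) -> None:
    pd.concat([dataset_to_frame(d) for d in datasets], ignore_index=True).to_csv(path, index=False)
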