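"""Synthetic tokens-task cohorts for fitting and recovery experiments.

Emulates the structure of the human tokens-task dataset: each subject
contributes trials of 15 fair-coin token movements at 200 ms intervals under
one animation-speed condition (slow or fast), with a single binned response
time per trial.  Subjects are generated from one of the three observer
models with known parameters, which makes parameter- and model-recovery
experiments possible; real human data are deliberately not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contexts import TOKENS_TOTAL, make_tokens_context
from .fit import PARAM_BOUNDS, PARAM_NAMES, SubjectDataset, model_kind_of, params_to_vector
from .simulate import ConstParams, NBParams, UGMParams, simulate_tokens_trials

__all__ = [
    "CohortSpec",
    "COHORT_PARAM_RANGES",
    "generate_token_sequences",
    "generate_synthetic_subject",
    "sample_params",
    "generate_cohort",
]

#: parameter ranges used when sampling synthetic subjects; chosen to span the
#: qualitatively distinct threshold regimes while keeping every subject inside
#: the fitting priors.  Noise ranges centre on a moderate noise strength.
COHORT_PARAM_RANGES = {
    "nb": {"Rc": (1.0, 8.0), "c": (0.1, 1.5), "sigma_y": (0.2, 1.5), "sigma_mn": (0.02, 0.15)},
    "const": {"theta0": (0.5, 3.0), "sigma_y": (0.2, 1.5), "sigma_mn": (0.02, 0.15)},
    "ugm": {"theta0": (0.2, 0.6), "a": (0.8, 2.0), "sigma_y": (0.2, 0.8),
            "tau": (0.1, 0.35), "sigma_mn": (0.02, 0.15)},
}

_PARAM_CLASSES = {"nb": NBParams, "const": ConstParams, "ugm": UGMParams}


@dataclass(frozen=True)
class CohortSpec:
    """Layout of a synthetic cohort."""

    n_subjects: int = 20
    trials_per_subject: int = 400
    model_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)  # NB, Const, UGM
    speed_mix: tuple[float, float] = (0.5, 0.5)  # slow, fast
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.trials_per_subject <= 0:
            raise ValueError("cohort counts must be positive")
        if abs(sum(self.model_mix) - 1.0) > 1e-9:
            raise ValueError("model mix proportions must sum to 1")
        if abs(sum(self.speed_mix) - 1.0) > 1e-9:
            raise ValueError("speed mix proportions must sum to 1")


def generate_token_sequences(n_trials: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """(n_trials, 15) independent fair-coin token movements, +1 = up."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(rng)
    return rng.choice([-1, 1], size=(n_trials, TOKENS_TOTAL))


def sample_params(model_kind: str, rng: np.random.Generator | int | None = None):
    """Draw one subject's generating parameters uniformly over the cohort ranges."""
    rng = np.random.default_rng(rng)
    ranges = COHORT_PARAM_RANGES[model_kind]
    values = {name: rng.uniform(*ranges[name]) for name in PARAM_NAMES[model_kind]}
    return _PARAM_CLASSES[model_kind](**values)


def generate_synthetic_subject(model_kind: str, params, speed: str, n_trials: int,
                               rng: np.random.Generator | int | None = None,
                               subject_id: str = "s0") -> SubjectDataset:
    """Simulate one synthetic subject's dataset from a known generator model."""
    if model_kind_of(params) != model_kind:
        raise ValueError("params do not match the requested model kind")
    vec = params_to_vector(params)
    for v, name in zip(vec, PARAM_NAMES[model_kind]):
        lo, hi = PARAM_BOUNDS[name]
        if not (lo <= v <= hi):
            raise ValueError(f"{name}={v} outside the prior bounds [{lo}, {hi}]")
    rng = np.random.default_rng(rng)
    seqs = generate_token_sequences(n_trials, rng)
    ctx = make_tokens_context(speed, Rc=1.0, cost=0.0)
    thresholds = None
    if isinstance(params, NBParams):
        from .fit import _nb_thresholds

        ctx, thresholds = _nb_thresholds(params.Rc, params.c, speed)
    df = simulate_tokens_trials(params, seqs, ctx, rng=rng, thresholds=thresholds)
    return SubjectDataset(seqs, df["rt_bin"].to_numpy(), speed, subject_id)


def generate_cohort(spec: CohortSpec):
    """Generate a cohort; returns a list of (dataset, model_kind, params)."""
    rng = np.random.default_rng(spec.master_seed)
    kinds = rng.choice(["nb", "const", "ugm"], size=spec.n_subjects, p=spec.model_mix)
    speeds = rng.choice(["slow", "fast"], size=spec.n_subjects, p=spec.speed_mix)
    out = []
    for i, (kind, speed) in enumerate(zip(kinds, speeds)):
        params = sample_params(kind, rng)
        data = generate_synthetic_subject(kind, params, speed, spec.trials_per_subject,
                                          rng, subject_id=f"s{i:03d}")
        out.append((data, kind, params))
    return out
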