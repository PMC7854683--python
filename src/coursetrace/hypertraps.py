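"""Reduced hypercubic Bayesian model for task-acquisition sequences.

The general Markov model on acquired-task subsets lives on a hypercube of
``2^T`` states with ``T·2^(T-1)`` transition edges — intractable at course
scale.  Following the HyperTraPS family of accumulation models, we reduce
it to ``T^2`` parameters: a T×T matrix θ whose diagonal ``θ_jj`` is the
basal log-propensity of acquiring task *j* and whose off-diagonal ``θ_ij``
is the additive log-influence of already-acquired task *i* on task *j*.
From acquired set A the next task is

    P(j | A) = w_j / Σ_{j'∉A} w_{j'},     log w_j = θ_jj + Σ_{i∈A} θ_ij.

Because completion order is fully observed here, the sequence likelihood
is the exact product of these step probabilities — no path sampling over
hidden orderings is needed.  Adding a constant to every diagonal entry
leaves all step distributions unchanged (only propensity contrasts are
identifiable).

Inference is random-walk Metropolis over θ under independent uniform
priors, with proposal-scale adaptation during burn-in only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sequence_core import LearnerRecord

__all__ = [
    "ModelConfig",
    "PosteriorSamples",
    "MCMCDiagnosticError",
    "n_parameters",
    "next_task_distribution",
    "sequence_loglik",
    "cohort_loglik",
    "simulate_sequence",
    "enumerate_order_probabilities",
    "fit_mcmc",
]


class MCMCDiagnosticError(RuntimeError):
    """Raised when a chain shows pathological behaviour (e.g. no accepted
    move over the whole run)."""


@dataclass(frozen=True)
class ModelConfig:
    """MCMC settings and the prior box.

    Priors are independent uniform on ``[prior_low, prior_high]`` per θ
    entry.  The spherical Gaussian proposal scale is adapted towards
    ``target_acceptance`` during burn-in and frozen afterwards.  A seed is
    mandatory: every fit is reproducible.
    """

    seed: int
    chain_length: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    prior_low: float = -10.0
    prior_high: float = 10.0
    proposal_scale: float = 0.1
    target_acceptance: float = 0.234
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if not (self.prior_low < self.prior_high):
            raise ValueError("prior_low must be below prior_high")
        if not (0 <= self.burn_in < self.chain_length):
            raise ValueError("need 0 <= burn_in < chain_length")
        if self.thin < 1 or self.proposal_scale <= 0:
            raise ValueError("thin >= 1 and proposal_scale > 0 required")


@dataclass(frozen=True)
class PosteriorSamples:
    """Thinned post-burn-in θ draws with their log-likelihoods."""

    draws: np.ndarray  # (M, T, T)
    loglik: np.ndarray  # (M,)
    acceptance_rate: float
    config: ModelConfig

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def T(self) -> int:
        return self.draws.shape[1]

    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def credible_interval(self, level: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
        alpha = (1.0 - level) / 2.0
        lo = np.quantile(self.draws, alpha, axis=0)
        hi = np.quantile(self.draws, 1.0 - alpha, axis=0)
        return lo, hi

    def save(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("draws", data=self.draws)
            f.create_dataset("loglik", data=self.loglik)
            f.attrs["acceptance_rate"] = self.acceptance_rate
            for k, v in vars(self.config).items():
                f.attrs[f"config_{k}"] = v

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        import h5py

        with h5py.File(path, "r") as f:
            draws = f["draws"][...]
            loglik = f["loglik"][...]
            acc = float(f.attrs["acceptance_rate"])
            cfg_kwargs = {
                k[len("config_") :]: v.item() if hasattr(v, "item") else v
                for k, v in f.attrs.items()
                if k.startswith("config_")
            }
            cfg_kwargs["seed"] = int(cfg_kwargs["seed"])
        return cls(
            draws=draws,
            loglik=loglik,
            acceptance_rate=acc,
            config=ModelConfig(**cfg_kwargs),
        )


def n_parameters(T: int) -> int:
    """Size of the reduced parameterisation: T² entries (e.g. 15,129 for a
    123-task course) versus the 2^T-state full hypercube."""
    return T * T


def _validate_theta(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError("theta must be a square matrix")
    if theta.shape[0] < 2:
        raise ValueError("theta needs T >= 2")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta entries must be finite")
    return theta


def next_task_distribution(
    theta: np.ndarray, acquired: Sequence[int]
) -> np.ndarray:
    """Distribution of the next task given the acquired set.

    Returns a length-T vector (index t−1 holds P(task t next)); acquired
    tasks get probability zero.  Computed in log space for stability.
    """
    theta = _validate_theta(theta)
    T = theta.shape[0]
    acq = np.asarray(sorted(set(acquired)), dtype=int)
    if acq.size and (acq[0] < 1 or acq[-1] > T):
        raise ValueError("acquired tasks must be in 1..T")
    if acq.size == T:
        raise ValueError("all tasks acquired: no next task exists")
    logw = np.diag(theta).copy()
    if acq.size:
        logw += theta[acq - 1].sum(axis=0)
    mask = np.zeros(T, dtype=bool)
    mask[acq - 1] = True
    logw[mask] = -np.inf
    p = np.exp(logw - logsumexp(logw))
    p[mask] = 0.0
    return p / p.sum()


def _step_arrays(sequences: Sequence[Sequence[int]], T: int):
    """Flatten sequences into (chosen, acquired-mask) step arrays.

    Step *m* of a sequence records which task was chosen (0-based) and the
    boolean mask of tasks acquired before it; all learners' steps are
    stacked so the cohort log-likelihood is two matrix products.
    """
    chosen: list[int] = []
    masks: list[np.ndarray] = []
    bounds = [0]
    for seq in sequences:
        m = np.zeros(T, dtype=bool)
        for t in seq:
            if not 1 <= t <= T:
                raise ValueError(f"task {t} outside 1..{T}")
            if m[t - 1]:
                raise ValueError(f"task {t} repeated in sequence")
            chosen.append(t - 1)
            masks.append(m.copy())
            m[t - 1] = True
        bounds.append(len(chosen))
    c = np.asarray(chosen, dtype=np.intp)
    a = (
        np.asarray(masks, dtype=bool)
        if masks
        else np.zeros((0, T), dtype=bool)
    )
    return c, a, np.asarray(bounds, dtype=np.intp)


def _steps_loglik(theta: np.ndarray, chosen: np.ndarray, amask: np.ndarray) -> np.ndarray:
    """Log step-probabilities for pre-flattened steps (vectorised)."""
    if chosen.size == 0:
        return np.zeros(0)
    logw = np.diag(theta)[None, :] + amask.astype(float) @ theta
    logw_open = np.where(amask, -np.inf, logw)
    lse = logsumexp(logw_open, axis=1)
    return logw[np.arange(chosen.size), chosen] - lse


def sequence_loglik(
    theta: np.ndarray, record: LearnerRecord | Sequence[int]
) -> float:
    """Exact log-probability of one observed (possibly partial) sequence.

    Only the observed steps contribute; there is no stopping-time term, so
    likelihoods of prefixes of different lengths remain comparable.
    """
    theta = _validate_theta(theta)
    seq = record.sequence if isinstance(record, LearnerRecord) else tuple(record)
    chosen, amask, _ = _step_arrays([seq], theta.shape[0])
    return float(_steps_loglik(theta, chosen, amask).sum())


def cohort_loglik(
    theta: np.ndarray, records: Sequence[LearnerRecord | Sequence[int]]
) -> float:
    """Sum of sequence log-likelihoods over a set of learners."""
    theta = _validate_theta(theta)
    seqs = [
        r.sequence if isinstance(r, LearnerRecord) else tuple(r) for r in records
    ]
    chosen, amask, _ = _step_arrays(seqs, theta.shape[0])
    return float(_steps_loglik(theta, chosen, amask).sum())


def simulate_sequence(
    theta: np.ndarray,
    length: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, ...]:
    """Draw one acquisition sequence step-by-step from the model.

    ``length=None`` acquires all T tasks; otherwise the draw is truncated
    after ``length`` steps.
    """
    theta = _validate_theta(theta)
    T = theta.shape[0]
    n = T if length is None else min(int(length), T)
    if n < 0:
        raise ValueError("length must be non-negative")
    rng = np.random.default_rng(rng)
    logw = np.diag(theta).copy()
    open_mask = np.ones(T, dtype=bool)
    seq: list[int] = []
    for _ in range(n):
        lw = np.where(open_mask, logw, -np.inf)
        p = np.exp(lw - logsumexp(lw))
        p[~open_mask] = 0.0
        p /= p.sum()
        t = int(rng.choice(T, p=p))
        seq.append(t + 1)
        open_mask[t] = False
        logw = logw + theta[t]
    return tuple(seq)


def enumerate_order_probabilities(theta: np.ndarray) -> dict[tuple[int, ...], float]:
    """Exhaustive probability of every full ordering (brute-force oracle).

    Evaluates all T! step products exactly; refused above T = 8.
    """
    theta = _validate_theta(theta)
    T = theta.shape[0]
    if T > 8:
        raise ValueError("exhaustive enumeration limited to T <= 8")
    out: dict[tuple[int, ...], float] = {}
    for perm in itertools.permutations(range(1, T + 1)):
        logw = np.diag(theta).copy()
        open_mask = np.ones(T, dtype=bool)
        logp = 0.0
        for t in perm:
            lw = np.where(open_mask, logw, -np.inf)
            logp += lw[t - 1] - logsumexp(lw)
            open_mask[t - 1] = False
            logw = logw + theta[t - 1]
        out[perm] = math.exp(logp)
    return out


def fit_mcmc(
    records: Sequence[LearnerRecord | Sequence[int]],
    T: int,
    config: ModelConfig,
) -> PosteriorSamples:
    """Random-walk Metropolis over θ for a set of observed sequences.

    The chain starts at θ = 0, perturbs all T² entries with a spherical
    Gaussian, rejects moves leaving the uniform prior box, adapts the
    proposal scale every ``adapt_interval`` iterations during burn-in, and
    returns thinned post-burn-in draws with their log-likelihood trace.
    """
    seqs = [
        r.sequence if isinstance(r, LearnerRecord) else tuple(r) for r in records
    ]
    if not seqs:
        raise ValueError("need at least one record")
    chosen, amask, _ = _step_arrays(seqs, T)
    amask_f = amask.astype(float)
    diag_idx = np.arange(T)

    def loglik(theta: np.ndarray) -> float:
        if chosen.size == 0:
            return 0.0
        logw = theta[diag_idx, diag_idx][None, :] + amask_f @ theta
        logw_open = np.where(amask, -np.inf, logw)
        lse = logsumexp(logw_open, axis=1)
        return float((logw[np.arange(chosen.size), chosen] - lse).sum())

    rng = np.random.default_rng(config.seed)
    theta = np.zeros((T, T))
    ll = loglik(theta)
    scale = config.proposal_scale

    draws: list[np.ndarray] = []
    lls: list[float] = []
    n_accept = 0
    window_accept = 0
    for it in range(config.chain_length):
        prop = theta + rng.normal(scale=scale, size=(T, T))
        if np.all((prop >= config.prior_low) & (prop <= config.prior_high)):
            ll_prop = loglik(prop)
            if math.log(rng.random()) < ll_prop - ll:
                theta, ll = prop, ll_prop
                n_accept += 1
                window_accept += 1
        in_burn = it < config.burn_in
        if in_burn and (it + 1) % config.adapt_interval == 0:
            rate = window_accept / config.adapt_interval
            # damped update, capped at the prior box width, so a flat
            # likelihood cannot blow the scale up faster than it recovers
            scale *= math.exp(0.5 * (rate - config.target_acceptance))
            scale = min(scale, config.prior_high - config.prior_low)
            window_accept = 0
        if not in_burn and (it - config.burn_in) % config.thin == 0:
            draws.append(theta.copy())
            lls.append(ll)

    if n_accept == 0:
        raise MCMCDiagnosticError(
            "no proposal accepted over the whole chain; "
            "try a smaller proposal_scale"
        )
    return PosteriorSamples(
        draws=np.asarray(draws),
        loglik=np.asarray(lls),
        acceptance_rate=n_accept / config.chain_length,
        config=config,
    )
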