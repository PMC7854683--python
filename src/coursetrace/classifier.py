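"""Posterior-odds classification of learners from sequence prefixes.

With posterior θ-samples fitted separately to two labelled groups, the
odds that learner *k* with prefix s^(k) belongs to group 1 are

    P(g1 | s) / P(g2 | s) = P(s | post_g1) P(g1) / (P(s | post_g2) P(g2)),

where P(s | post) is the posterior-predictive likelihood: the average over
posterior draws of the exact sequence likelihood (computed with
log-sum-exp).  Evaluating at every prefix length n gives a membership
trajectory per learner; group mean curves and the proportion above 0.5
summarise the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .hypertraps import ModelConfig, PosteriorSamples, fit_mcmc
from .sequence_core import Cohort, GroupLabelling, LearnerRecord

__all__ = [
    "MembershipTrajectory",
    "SplitEvaluation",
    "group_marginal_loglik",
    "membership_probability",
    "classification_trajectories",
    "evaluate_split",
]


@dataclass(frozen=True)
class MembershipTrajectory:
    """P(g1 | first n tasks) for a set of learners, n = 1..max length.

    ``probs[k, n-1]`` is learner k's membership probability after n tasks
    (NaN past their last completion); ``mean_curve`` and
    ``prop_above_half`` aggregate over the learners defined at each n.
    """

    learner_ids: tuple[str, ...]
    true_labels: tuple[str, ...]
    probs: np.ndarray
    prior_g1: float

    @property
    def n_max(self) -> int:
        return self.probs.shape[1]

    @property
    def mean_curve(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.probs, axis=0)

    @property
    def prop_above_half(self) -> np.ndarray:
        defined = ~np.isnan(self.probs)
        above = (self.probs > 0.5) & defined
        with np.errstate(invalid="ignore"):
            return above.sum(axis=0) / defined.sum(axis=0)


def _prefix_marginal_logliks(
    seq: Sequence[int], posterior: PosteriorSamples, average: str
) -> np.ndarray:
    """Marginal log-likelihood of every prefix of ``seq`` under a posterior.

    Per draw, prefix log-likelihoods are cumulative sums of step log
    probabilities, so one pass gives all n at once.  ``average``:
    'likelihood' (posterior predictive, default) averages the likelihoods
    across draws; 'loglik' averages the log-likelihoods.
    """
    T = posterior.T
    L = len(seq)
    if L == 0:
        return np.zeros(0)
    amask = np.zeros((L, T), dtype=float)
    chosen = np.zeros(L, dtype=np.intp)
    m = np.zeros(T, dtype=bool)
    for i, t in enumerate(seq):
        chosen[i] = t - 1
        amask[i, :] = m
        m[t - 1] = True
    thetas = posterior.draws  # (M, T, T)
    diag = thetas[:, np.arange(T), np.arange(T)]  # (M, T)
    logw = diag[:, None, :] + np.matmul(amask, thetas)  # (M, L, T)
    logw_open = np.where(amask[None, :, :] > 0, -np.inf, logw)
    lse = logsumexp(logw_open, axis=2)  # (M, L)
    step_ll = logw[:, np.arange(L), chosen] - lse  # (M, L)
    cum = np.cumsum(step_ll, axis=1)  # per-draw prefix logliks
    if average == "likelihood":
        return logsumexp(cum, axis=0) - math.log(thetas.shape[0])
    if average == "loglik":
        return cum.mean(axis=0)
    raise ValueError("average must be 'likelihood' or 'loglik'")


def group_marginal_loglik(
    prefix: LearnerRecord | Sequence[int],
    posterior: PosteriorSamples,
    average: str = "likelihood",
) -> float:
    """Posterior-predictive log-likelihood of a (possibly partial) sequence:
    log of the draw-averaged likelihood, via log-sum-exp."""
    seq = prefix.sequence if isinstance(prefix, LearnerRecord) else tuple(prefix)
    if len(seq) == 0:
        return 0.0
    return float(_prefix_marginal_logliks(seq, posterior, average)[-1])


def membership_probability(
    prefix: LearnerRecord | Sequence[int],
    post_g1: PosteriorSamples,
    post_g2: PosteriorSamples,
    prior_g1: float = 0.5,
    average: str = "likelihood",
) -> float:
    """P(g1 | prefix) from the posterior-odds ratio."""
    if not 0.0 < prior_g1 < 1.0:
        raise ValueError("prior_g1 must lie strictly between 0 and 1")
    a = group_marginal_loglik(prefix, post_g1, average)
    b = group_marginal_loglik(prefix, post_g2, average)
    log_odds = a - b + math.log(prior_g1) - math.log(1.0 - prior_g1)
    return 1.0 / (1.0 + math.exp(-log_odds))


def classification_trajectories(
    records: Sequence[LearnerRecord],
    post_g1: PosteriorSamples,
    post_g2: PosteriorSamples,
    true_labels: Sequence[str] | None = None,
    prior_g1: float = 0.5,
    average: str = "likelihood",
) -> MembershipTrajectory:
    """Membership probability at every prefix length for each learner."""
    if not records:
        raise ValueError("need at least one record")
    if not 0.0 < prior_g1 < 1.0:
        raise ValueError("prior_g1 must lie strictly between 0 and 1")
    if true_labels is None:
        true_labels = [""] * len(records)
    n_max = max((len(r.sequence) for r in records), default=0)
    probs = np.full((len(records), max(n_max, 1)), np.nan)
    log_prior_odds = math.log(prior_g1) - math.log(1.0 - prior_g1)
    for k, rec in enumerate(records):
        if len(rec.sequence) == 0:
            continue
        a = _prefix_marginal_logliks(rec.sequence, post_g1, average)
        b = _prefix_marginal_logliks(rec.sequence, post_g2, average)
        log_odds = a - b + log_prior_odds
        probs[k, : len(rec.sequence)] = 1.0 / (1.0 + np.exp(-log_odds))
    return MembershipTrajectory(
        learner_ids=tuple(r.learner_id for r in records),
        true_labels=tuple(true_labels),
        probs=probs,
        prior_g1=prior_g1,
    )


@dataclass(frozen=True)
class SplitEvaluation:
    """Both evaluation protocols for a two-group cohort.

    ``insample``: posteriors fitted on every group member, evaluated on the
    same members.  ``holdout``: fitted on a seeded stratified train split,
    evaluated on the held-out members.  Keys of each dict are the group
    labels.
    """

    insample: dict[str, MembershipTrajectory]
    holdout: dict[str, MembershipTrajectory]
    train_ids: dict[str, tuple[str, ...]]
    test_ids: dict[str, tuple[str, ...]]


def evaluate_split(
    cohort: Cohort,
    groups: GroupLabelling,
    config: ModelConfig,
    labels: tuple[str, str] = ("g1", "g2"),
    train_fraction: float = 0.7,
    seed: int = 0,
    prior_g1: float = 0.5,
    average: str = "likelihood",
) -> SplitEvaluation:
    """Run the in-sample and held-out classification protocols.

    The train/test split is stratified by group and seeded; each group
    contributes ``floor(train_fraction * size)`` training learners.  Four
    model fits are performed (per group: all members, and train split).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    la, lb = labels
    members = {lab: groups.members(lab) for lab in labels}
    for lab in labels:
        if len(members[lab]) < 2:
            raise ValueError(f"group {lab!r} too small to split")

    rng = np.random.default_rng(seed)
    train_ids: dict[str, tuple[str, ...]] = {}
    test_ids: dict[str, tuple[str, ...]] = {}
    for lab in labels:
        ids = list(members[lab])
        n_train = math.floor(train_fraction * len(ids))
        if n_train == 0 or n_train == len(ids):
            raise ValueError(f"group {lab!r} too small for a {train_fraction} split")
        perm = rng.permutation(len(ids))
        train_ids[lab] = tuple(ids[i] for i in perm[:n_train])
        test_ids[lab] = tuple(ids[i] for i in perm[n_train:])

    T = cohort.catalog.T

    def _records(ids: Sequence[str]) -> list[LearnerRecord]:
        return [cohort.learner(i) for i in ids]

    def _cfg(offset: int) -> ModelConfig:
        # independent, reproducible seed per fit
        return ModelConfig(**{**vars(config), "seed": config.seed + offset})

    post_full = {
        lab: fit_mcmc(_records(members[lab]), T, _cfg(i))
        for i, lab in enumerate(labels)
    }
    post_train = {
        lab: fit_mcmc(_records(train_ids[lab]), T, _cfg(2 + i))
        for i, lab in enumerate(labels)
    }

    insample = {
        lab: classification_trajectories(
            _records(members[lab]),
            post_full[la],
            post_full[lb],
            true_labels=[lab] * len(members[lab]),
            prior_g1=prior_g1,
            average=average,
        )
        for lab in labels
    }
    holdout = {
        lab: classification_trajectories(
            _records(test_ids[lab]),
            post_train[la],
            post_train[lb],
            true_labels=[lab] * len(test_ids[lab]),
            prior_g1=prior_g1,
            average=average,
        )
        for lab in labels
    }
    return SplitEvaluation(
        insample=insample,
        holdout=holdout,
        train_ids=train_ids,
        test_ids=test_ids,
    )
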