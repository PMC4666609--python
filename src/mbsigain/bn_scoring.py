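"""Local Bayesian-network scores for a target given a candidate parent set.

Three criteria are provided for the single-node model in which the
predictors in a set ``PA`` are the parents of the target ``Z``:

* the Bayesian (Dirichlet) marginal likelihood, a double product of
  Gamma-function ratios over parent instantiations ``j`` and target
  states ``k`` with hyperparameters ``a_jk``;
* its BDeu specialization, where a single prior equivalent sample size
  ``alpha`` sets ``a_jk = alpha / (r q)`` (a prior uniform distribution
  for the node);
* the MDL description length ``d log2(m)/2 - m IG(Z; PA)`` with
  ``d = (r - 1) q`` free parameters, where IG is the plug-in information
  gain computed from the data.  Smaller MDL is better.

All Bayesian scores live in log space (the raw Gamma products overflow
for realistic m), and every search compares models on a single unified
higher-is-better ``fitness``: the BDeu log score directly, or the
negated MDL score.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln

from .core_data import (
    ContingencyCounts,
    DegenerateInputError,
    GenotypeDataset,
    InputError,
    count_table,
)

__all__ = [
    "Criterion",
    "ScoreParams",
    "bayesian_log_score",
    "bdeu_log_score",
    "mdl_score",
    "fitness",
    "fitness_from_counts",
    "rank_single_predictors",
    "model_sort_key",
]

logger = logging.getLogger(__name__)


class Criterion(str, enum.Enum):
    """Scoring criterion for parent-set models."""

    BDEU = "bdeu"
    MDL = "mdl"


@dataclass(frozen=True)
class ScoreParams:
    """Scoring configuration, fixed for a whole search run.

    ``alpha`` is the BDeu prior equivalent sample size (> 0); the
    hyperparameters are derived as ``alpha / (r q)``.  Defaults: MDL
    criterion, alpha = 4 (the headline BDeu setting when BDeu is used;
    a small alpha keeps the structure prior weak).
    """

    criterion: Criterion = Criterion.MDL
    alpha: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "criterion", Criterion(self.criterion))
        if self.alpha <= 0:
            raise InputError("alpha (prior equivalent sample size) must be > 0")


def bayesian_log_score(counts: ContingencyCounts, a_jk: np.ndarray) -> float:
    """Log marginal likelihood of the data for the single target node.

    ``a_jk`` is the (q, r) grid of Dirichlet hyperparameters (a scalar
    broadcasts).  The value is the log of the double product of
    Gamma-ratio terms; m = 0 gives log(1) = 0.
    """
    a_in = np.asarray(a_jk, dtype=float)
    if a_in.ndim >= 1 and a_in.shape != (counts.q, counts.r):
        raise InputError(
            f"hyperparameter grid shape {a_in.shape} != (q={counts.q}, r={counts.r})"
        )
    a = np.broadcast_to(a_in, (counts.q, counts.r))
    if (a <= 0).any():
        raise InputError("hyperparameters a_jk must be strictly positive")
    s = counts.counts.astype(float)
    a_j = a.sum(axis=1)
    s_j = s.sum(axis=1)
    per_j = gammaln(a_j) - gammaln(a_j + s_j) + (gammaln(a + s) - gammaln(a)).sum(axis=1)
    return float(per_j.sum())


def bdeu_log_score(counts: ContingencyCounts, alpha: float) -> float:
    """BDeu log score: the Bayesian score with uniform hyperparameters
    ``a_jk = alpha / (r q)``."""
    if alpha <= 0:
        raise InputError("alpha must be > 0")
    return bayesian_log_score(counts, alpha / (counts.r * counts.q))


def _plugin_ig_bits(counts: ContingencyCounts) -> float:
    """IG(Z; PA) from a count grid: the empirical mutual information
    sum_jk P(j,k) log2( P(j,k) / (P(k) P(j)) ), in bits."""
    s = counts.counts.astype(float)
    m = float(counts.m)
    p = s / m
    pj = p.sum(axis=1, keepdims=True)
    pk = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (pj * pk), 1.0)
        terms = np.where(p > 0, p * np.log2(ratio), 0.0)
    return float(terms.sum())


def mdl_param_count(counts: ContingencyCounts) -> int:
    """Free parameters of the target's conditional distributions:
    d = (r - 1) q."""
    return (counts.r - 1) * counts.q


def mdl_score(counts: ContingencyCounts) -> float:
    """MDL description length d log2(m)/2 - m IG(Z; PA); smaller is
    better.  The empty parent set (q = 1) has IG = 0."""
    if counts.m == 0:
        raise DegenerateInputError("MDL score is undefined for m = 0")
    m = float(counts.m)
    return mdl_param_count(counts) * np.log2(m) / 2.0 - m * _plugin_ig_bits(counts)


def fitness_from_counts(counts: ContingencyCounts, params: ScoreParams) -> float:
    """Unified higher-is-better fitness of a parent-set model."""
    if params.criterion is Criterion.BDEU:
        return bdeu_log_score(counts, params.alpha)
    return -mdl_score(counts)


def raw_score_from_counts(counts: ContingencyCounts, params: ScoreParams) -> float:
    """The criterion's native value (BDeu log score; MDL description
    length, for which smaller is better)."""
    if params.criterion is Criterion.BDEU:
        return bdeu_log_score(counts, params.alpha)
    return mdl_score(counts)


def fitness(
    dataset: GenotypeDataset, predictor_set: Iterable[str], params: ScoreParams
) -> float:
    """Fitness of the model with ``predictor_set`` as parents of the
    target.  BDeu is maximized and MDL minimized natively; both are
    mapped onto one higher-is-better scale so the searches compare
    models uniformly."""
    return fitness_from_counts(count_table(dataset, predictor_set), params)


def model_sort_key(predictor_set: Iterable[str], fit: float):
    """Deterministic ordering for scored models: larger fitness first,
    ties broken by smaller set size, then lexicographic identifiers."""
    members = tuple(sorted(predictor_set))
    return (-fit, len(members), members)


def rank_single_predictors(
    dataset: GenotypeDataset, params: ScoreParams, n: int
) -> list[str]:
    """The ``n`` predictors whose one-parent models score highest,
    sorted by descending fitness (deterministic tie-break).  This is the
    prefilter that selects the most promising predictors before beams
    are started."""
    if n < 1:
        raise InputError("prefilter size n must be >= 1")
    scored = [
        (pid, fitness(dataset, [pid], params)) for pid in dataset.predictor_ids
    ]
    scored.sort(key=lambda t: model_sort_key([t[0]], t[1]))
    if n > len(scored):
        logger.info(
            "prefilter size %d exceeds the %d available predictors; returning all",
            n,
            len(scored),
        )
        n = len(scored)
    return [pid for pid, _ in scored[:n]]
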