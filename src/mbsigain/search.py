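"""Multiple-beam interaction searches: MBS-IGain, MBS and REGAL.

All three start one greedy beam per prefiltered predictor and score
candidate parent sets of the target with a Bayesian-network criterion
(BDeu or MDL).  They differ in how beams grow:

* **MBS-IGain** adds, at each step, the predictor with the greatest
  interaction strength (IS) with the predictors already on the beam, and
  stops when the IS is small relative to the individual information
  gains (ratio threshold ``T``), when adding the predictor would lower
  the model score, or when ``M`` predictors have been added.  Growth by
  IS finds predictors that *interact*; the score stop keeps only likely
  models.
* **MBS** grows by greatest score improvement until no addition helps
  (capped at ``M`` additions), then greedily deletes predictors while a
  deletion improves the score.  Strong-marginal predictors tend to be
  absorbed because they raise the score even without interacting.
* **REGAL** repeatedly runs MBS (default 5 iterations), removing the
  predictors of the highest-scoring model from the candidate pool after
  each iteration so lower-scoring interactions can surface.

Per beam the work is O(candidate pool) IS or score evaluations per
added predictor, so a full run is O(n * M * n) evaluations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bn_scoring import (
    ScoreParams,
    fitness_from_counts,
    model_sort_key,
    raw_score_from_counts,
    rank_single_predictors,
    _plugin_ig_bits,
)
from .core_data import (
    ContingencyCounts,
    GenotypeDataset,
    InputError,
    ScoredModel,
)
from .info_theory import clamp_nonneg

__all__ = ["SearchParams", "mbs_igain", "mbs", "regal"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchParams:
    """Configuration shared by the three searches.

    Parameters
    ----------
    score
        Scoring criterion configuration (criterion and BDeu alpha).
    T
        IS-ratio stopping threshold for MBS-IGain (>= 0).  A beam stops
        when IS(Z; G, X) / (IG(Z; G) + IG(Z; X)) <= T.  Default 0.1.
    M
        Maximum number of predictors *added* per beam, so models contain
        at most M + 1 predictors.  Default 4.
    n
        Prefilter size: beams are started from the n best-scoring
        1-predictor models.  ``None`` starts a beam from every predictor.
    regal_iterations
        Number of MBS rounds REGAL runs, each time deleting the top
        model's predictors from the pool.  Default 5.
    """

    score: ScoreParams = field(default_factory=ScoreParams)
    T: float = 0.1
    M: int = 4
    n: int | None = None
    regal_iterations: int = 5

    def __post_init__(self) -> None:
        if self.T < 0:
            raise InputError("threshold T must be >= 0")
        if self.M < 0:
            raise InputError("M must be >= 0")
        if self.n is not None and self.n < 1:
            raise InputError("prefilter size n must be >= 1")
        if self.regal_iterations < 1:
            raise InputError("regal_iterations must be >= 1")


# ---------------------------------------------------------------------------
# Incremental counting helpers.  Beam growth composes mixed-radix parent
# codes incrementally; information gain, BDeu and MDL all depend on the
# count grid only up to a relabelling of the instantiation index, so the
# incremental order is score-equivalent to the canonical column order.


class _Workspace:
    """Per-dataset cached columns and single-predictor statistics."""

    def __init__(self, dataset: GenotypeDataset, params: SearchParams):
        self.dataset = dataset
        self.params = params
        self.r = dataset.target_states
        self.target = dataset.target
        self.m = dataset.m
        self.cols = {pid: dataset.column_index(pid) for pid in dataset.predictor_ids}
        self.cards = {
            pid: dataset.states_per_predictor[self.cols[pid]]
            for pid in dataset.predictor_ids
        }
        self.codes = {pid: dataset.matrix[:, self.cols[pid]] for pid in dataset.predictor_ids}
        self._single_ig: dict[str, float] = {}
        self._single_fit: dict[str, float] = {}

    def counts(self, codes: np.ndarray, q: int) -> ContingencyCounts:
        flat = np.bincount(codes * self.r + self.target, minlength=q * self.r)
        return ContingencyCounts(r=self.r, q=q, counts=flat.reshape(q, self.r), m=self.m)

    def counts_for(self, pids: Sequence[str]) -> ContingencyCounts:
        codes = np.zeros(self.m, dtype=np.int64)
        q = 1
        for pid in pids:
            codes = codes * self.cards[pid] + self.codes[pid]
            q *= self.cards[pid]
        return self.counts(codes, q)

    def single_ig(self, pid: str) -> float:
        if pid not in self._single_ig:
            cc = self.counts(self.codes[pid].astype(np.int64), self.cards[pid])
            self._single_ig[pid] = clamp_nonneg(_plugin_ig_bits(cc))
        return self._single_ig[pid]

    def single_fitness(self, pid: str) -> float:
        if pid not in self._single_fit:
            cc = self.counts(self.codes[pid].astype(np.int64), self.cards[pid])
            self._single_fit[pid] = fitness_from_counts(cc, self.params.score)
        return self._single_fit[pid]

    def set_is(self, pids: Sequence[str], ig_joint: float) -> float:
        """Set interaction strength of ``pids`` given its joint IG."""
        if len(pids) < 2:
            return 0.0
        return clamp_nonneg(ig_joint - sum(self.single_ig(p) for p in pids))


def _prefilter(dataset: GenotypeDataset, params: SearchParams) -> list[str]:
    n = params.n if params.n is not None else dataset.n_predictors
    return rank_single_predictors(dataset, params.score, n)


def _finalize(
    ws: _Workspace, raw_models: list[tuple[list[str], float, float, str]]
) -> list[ScoredModel]:
    """Deduplicate by predictor set (best fitness kept) and sort by
    descending fitness with the deterministic tie-break."""
    best: dict[frozenset[str], tuple[list[str], float, float, str]] = {}
    for pids, fit, ig_joint, origin in raw_models:
        key = frozenset(pids)
        if key not in best or fit > best[key][1]:
            best[key] = (pids, fit, ig_joint, origin)
    models = []
    for pids, fit, ig_joint, origin in best.values():
        cc = ws.counts_for(sorted(pids, key=lambda p: ws.cols[p]))
        models.append(
            ScoredModel(
                predictor_set=frozenset(pids),
                fitness=fit,
                raw_score=raw_score_from_counts(cc, ws.params.score),
                interaction_strength=ws.set_is(pids, clamp_nonneg(_plugin_ig_bits(cc))),
                origin_beam=origin,
            )
        )
    models.sort(key=lambda sm: model_sort_key(sm.predictor_set, sm.fitness))
    return models


def _check_dataset(dataset: GenotypeDataset) -> None:
    if dataset.n_predictors < 1:
        raise InputError("dataset has no predictors")
    if dataset.m == 0:
        raise InputError("dataset has no rows")


def mbs_igain(
    dataset: GenotypeDataset,
    params: SearchParams | None = None,
    pool: Sequence[str] | None = None,
) -> list[ScoredModel]:
    """Interaction discovery by information-gain-driven multiple beam
    search.

    One beam is started from each prefiltered predictor.  At each step
    the candidate ``X`` (from the full prefiltered pool minus the beam)
    maximizing the data-estimated IS(Z; G, X) is found; the beam stops if

    * IS(Z; G, X) / (IG(Z; G) + IG(Z; X)) <= T (the interaction is small
      relative to the marginal gains; a zero denominator also stops —
      no information means no interaction evidence), or
    * fitness(G u {X}) < fitness(G) (the grown model is less likely), or
    * M predictors have already been added;

    otherwise ``X`` joins the beam.  Models are deduplicated by
    predictor set and returned sorted by descending fitness.
    """
    params = params or SearchParams()
    _check_dataset(dataset)
    ws = _Workspace(dataset, params)
    if pool is None:
        pool = _prefilter(dataset, params)
    pool = list(pool)
    raw: list[tuple[list[str], float, float, str]] = []
    for seed in pool:
        g = [seed]
        g_codes = ws.codes[seed].astype(np.int64)
        g_q = ws.cards[seed]
        ig_g = ws.single_ig(seed)
        fit_g = ws.single_fitness(seed)
        while len(g) < params.M + 1:
            g_set = set(g)
            best_x: str | None = None
            best_is = -np.inf
            best_ig_joint = 0.0
            best_codes: np.ndarray | None = None
            best_q = 0
            for x in sorted(p for p in pool if p not in g_set):
                codes = g_codes * ws.cards[x] + ws.codes[x]
                q = g_q * ws.cards[x]
                ig_joint = clamp_nonneg(_plugin_ig_bits(ws.counts(codes, q)))
                is_x = clamp_nonneg(ig_joint - ig_g - ws.single_ig(x))
                if is_x > best_is:
                    best_x, best_is = x, is_x
                    best_ig_joint, best_codes, best_q = ig_joint, codes, q
            if best_x is None:
                break  # pool exhausted
            denom = ig_g + ws.single_ig(best_x)
            if denom <= 0 or best_is / denom <= params.T:
                logger.debug(
                    "beam %s: stop on IS ratio (X=%s, IS=%.4g, denom=%.4g)",
                    seed, best_x, best_is, denom,
                )
                break
            fit_new = fitness_from_counts(ws.counts(best_codes, best_q), params.score)
            if fit_new < fit_g:
                logger.debug(
                    "beam %s: stop on score decrease (X=%s, %.4f -> %.4f)",
                    seed, best_x, fit_g, fit_new,
                )
                break
            g.append(best_x)
            g_codes, g_q, ig_g, fit_g = best_codes, best_q, best_ig_joint, fit_new
            logger.debug(
                "beam %s: added %s (IS=%.4g, ratio=%.4g, fitness=%.4f)",
                seed, best_x, best_is, best_is / denom, fit_new,
            )
        raw.append((g, fit_g, ig_g, seed))
    return _finalize(ws, raw)


def _mbs_beams(
    ws: _Workspace, pool: Sequence[str], params: SearchParams
) -> list[tuple[list[str], float, float, str]]:
    raw: list[tuple[list[str], float, float, str]] = []
    for seed in pool:
        g = [seed]
        g_codes = ws.codes[seed].astype(np.int64)
        g_q = ws.cards[seed]
        fit_g = ws.single_fitness(seed)
        # forward: add the predictor that increases the score the most
        for _ in range(params.M):
            g_set = set(g)
            best_x = None
            best_fit = -np.inf
            best_codes = None
            best_q = 0
            for x in sorted(p for p in pool if p not in g_set):
                codes = g_codes * ws.cards[x] + ws.codes[x]
                q = g_q * ws.cards[x]
                fit = fitness_from_counts(ws.counts(codes, q), params.score)
                if fit > best_fit:
                    best_x, best_fit, best_codes, best_q = x, fit, codes, q
            if best_x is None or best_fit <= fit_g:
                break
            g.append(best_x)
            g_codes, g_q, fit_g = best_codes, best_q, best_fit
        # backward: delete the predictor whose removal increases the
        # score the most, while a deletion helps; never below 1 member
        while len(g) > 1:
            best_del = None
            best_fit = fit_g
            for x in sorted(g):  # ties deleted in lexicographic order
                remaining = [p for p in g if p != x]
                fit = fitness_from_counts(ws.counts_for(remaining), params.score)
                if fit > best_fit:
                    best_del, best_fit = x, fit
            if best_del is None:
                break
            g.remove(best_del)
            fit_g = best_fit
            logger.debug("beam %s: deleted %s (fitness=%.4f)", seed, best_del, fit_g)
        cc = ws.counts_for(g)
        raw.append((g, fit_g, clamp_nonneg(_plugin_ig_bits(cc)), seed))
    return raw


def mbs(
    dataset: GenotypeDataset,
    params: SearchParams | None = None,
    pool: Sequence[str] | None = None,
) -> list[ScoredModel]:
    """Multiple beam search by score alone: greedy forward additions
    (capped at M) while the score improves, then greedy backward
    deletions while a deletion improves the score.  Output is
    deduplicated and sorted like :func:`mbs_igain`."""
    params = params or SearchParams()
    _check_dataset(dataset)
    ws = _Workspace(dataset, params)
    if pool is None:
        pool = _prefilter(dataset, params)
    return _finalize(ws, _mbs_beams(ws, list(pool), params))


def regal(
    dataset: GenotypeDataset,
    params: SearchParams | None = None,
    pool: Sequence[str] | None = None,
) -> list[ScoredModel]:
    """Iterated MBS: run MBS, delete the top model's predictors from the
    candidate pool, and repeat (``regal_iterations`` rounds, default 5)
    so that interactions masked by stronger ones can be found.  All
    discovered models are concatenated, deduplicated and sorted."""
    params = params or SearchParams()
    _check_dataset(dataset)
    ws = _Workspace(dataset, params)
    if pool is None:
        pool = _prefilter(dataset, params)
    pool = list(pool)
    raw: list[tuple[list[str], float, float, str]] = []
    for it in range(params.regal_iterations):
        if not pool:
            logger.info("REGAL: candidate pool exhausted after %d iterations", it)
            break
        round_models = _mbs_beams(ws, pool, params)
        round_models.sort(key=lambda t: model_sort_key(t[0], t[1]))
        raw.extend(round_models)
        top = set(round_models[0][0])
        logger.debug("REGAL iteration %d: removing %s", it + 1, sorted(top))
        pool = [p for p in pool if p not in top]
    return _finalize(ws, raw)
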