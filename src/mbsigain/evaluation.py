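"""Power criteria and ROC construction for ranked interaction output.

Two power criteria benchmark a method's ranked model list against a
planted truth of disjoint interaction groups:

* **Power1(K)** — predictor-level recall: predictors are ranked by the
  first (highest-scoring) model in which each appears, and power is the
  average fraction of causative predictors among the first K, i.e.
  ``(1 / (R * M)) * sum_i N_K(i)`` over R datasets with M causative
  predictors in total.
* **Power2(K, C)** — interaction-level recovery of one truth group C:
  per dataset, the best Jaccard index between C and any of the first K
  models, averaged with the same ``1 / (R * M)`` normalization.  With
  that normalization the criterion cannot reach 1 even on perfect
  recovery (the per-dataset maximum is 1, divided by M); the
  ``natural`` flag switches to the ``1 / R`` average instead.

ROC points report, for a cutoff m into the predictor ranking, the true
positive rate x / M and false positive rate y / (total - M), where x
and y are the causative and non-causative predictors among the top m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_data import InputError, ScoredModel

__all__ = [
    "TruthSpec",
    "predictor_ranking",
    "power1",
    "jaccard",
    "power2",
    "roc_points",
    "is_gain_ratio",
]


@dataclass(frozen=True)
class TruthSpec:
    """Planted interaction groups (disjoint predictor-identifier sets)."""

    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        seen: set[str] = set()
        for g in groups:
            if not g:
                raise InputError("truth groups must be non-empty")
            if seen & g:
                raise InputError("truth groups must be disjoint")
            seen |= g
        object.__setattr__(self, "_causative", frozenset(seen))

    @property
    def causative(self) -> frozenset[str]:
        return self._causative  # type: ignore[attr-defined]

    @property
    def m_true(self) -> int:
        """Total number of causative predictors (sum of group sizes)."""
        return len(self.causative)


def predictor_ranking(models: Sequence[ScoredModel]) -> list[str]:
    """Flatten a fitness-sorted model list into a predictor ranking:
    each predictor is ranked by the first model in which it appears;
    within one model, members are ordered lexicographically."""
    ranking: list[str] = []
    seen: set[str] = set()
    for model in models:
        for pid in model.sorted_members():
            if pid not in seen:
                seen.add(pid)
                ranking.append(pid)
    return ranking


def power1(
    model_lists: Sequence[Sequence[ScoredModel]], truth: TruthSpec, k: int
) -> float:
    """Criterion-1 power: average fraction of causative predictors
    ranked among the first ``k`` predictors, over datasets."""
    if k < 0:
        raise InputError("K must be >= 0")
    if not model_lists:
        raise InputError("need at least one dataset's models")
    total = 0
    for models in model_lists:
        top = set(predictor_ranking(models)[:k])
        total += len(top & truth.causative)
    return total / (len(model_lists) * truth.m_true)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |a n b| / |a u b|; 1 for identical sets, 0 for
    disjoint ones."""
    a, b = set(a), set(b)
    if not a and not b:
        raise InputError("Jaccard index of two empty sets is undefined")
    return len(a & b) / len(a | b)


def power2(
    model_lists: Sequence[Sequence[ScoredModel]],
    c: Iterable[str],
    truth: TruthSpec,
    k: int,
    natural: bool = False,
) -> float:
    """Criterion-2 power for one truth group ``c``: per dataset the best
    Jaccard index between ``c`` and any of the first ``k`` models, then
    averaged over datasets with the ``1 / (R * M)`` normalization
    (``natural=True`` uses ``1 / R`` so a perfectly recovered group
    scores 1)."""
    c = set(c)
    if not c:
        raise InputError("truth group c must be non-empty")
    if k < 1:
        raise InputError("K must be >= 1")
    if not model_lists:
        raise InputError("need at least one dataset's models")
    total = 0.0
    for models in model_lists:
        best = 0.0
        for model in models[:k]:
            best = max(best, jaccard(model.predictor_set, c))
        total += best
    denom = len(model_lists) * (1 if natural else truth.m_true)
    return total / denom


def is_gain_ratio(
    is_value: float, marginal_gain: float, ndigits: int = 2
) -> float:
    """How much a model's interaction strength adds on top of a single
    predictor's marginal information gain, as the rounded ratio
    IS / IG — the standard way a discovered interaction is reported
    relative to its strongest member (e.g. a model with IS 0.049 over a
    locus of gain 0.121 provides a 0.40 relative increase)."""
    if marginal_gain <= 0:
        raise InputError("marginal information gain must be positive")
    return round(is_value / marginal_gain, ndigits)


def _default_cutoffs(total_predictors: int) -> list[int]:
    if total_predictors <= 10_000:
        return list(range(0, total_predictors + 1))
    # logarithmic grid for very large universes
    cuts = {0, total_predictors}
    x = 1.0
    while x < total_predictors:
        cuts.add(int(round(x)))
        x *= 1.1
    return sorted(cuts)


def roc_points(
    ranking: Sequence[str],
    truth: TruthSpec,
    total_predictors: int,
    cutoffs: Sequence[int] | None = None,
    all_ids: Sequence[str] | None = None,
) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr) over cutoffs into a predictor ranking.

    At cutoff m, tpr = x / M and fpr = y / (total_predictors - M) with
    x causative and y non-causative predictors among the top m.  If
    ``all_ids`` is given, predictors absent from ``ranking`` are
    appended in identifier order so a partial ranking spans the full
    axis range."""
    if total_predictors <= truth.m_true:
        raise InputError("total_predictors must exceed the causative count")
    ranking = list(ranking)
    if all_ids is not None:
        seen = set(ranking)
        ranking += sorted(pid for pid in all_ids if pid not in seen)
    if cutoffs is None:
        cutoffs = _default_cutoffs(total_predictors)
    neg = total_predictors - truth.m_true
    points = []
    for m in cutoffs:
        top = ranking[: int(m)]
        x = sum(1 for pid in top if pid in truth.causative)
        y = len(top) - x
        points.append((y / neg, x / truth.m_true))
    return points
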