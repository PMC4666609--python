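"""Dataset and distribution containers plus the counting kernel.

Everything downstream — entropy, information gain, the Bayesian and MDL
scores — is built on contingency counts of a single discrete target ``Z``
against the joint instantiations of a candidate parent (predictor) set.
Only parent sets of one distinguished target are ever represented; no
general DAG machinery exists or is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenotypeDataset",
    "JointDistribution",
    "ContingencyCounts",
    "ScoredModel",
    "InputError",
    "DegenerateInputError",
    "count_table",
    "empirical_joint",
]


class InputError(ValueError):
    """Malformed or inconsistent user input (unknown ids, bad shapes...)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but degenerate (e.g. an empty dataset
    where probabilities are required)."""


@dataclass(frozen=True)
class GenotypeDataset:
    """A discrete predictor matrix with a discrete target.

    Rows are individuals; columns are predictors with small finite state
    spaces (for SNP data: genotype codes 0/1/2, copies of the minor
    allele).  The target is a separate per-individual code (for
    case-control data: 0 = control, 1 = case).

    Parameters
    ----------
    predictor_ids
        Unique column identifiers, in column order.
    states_per_predictor
        Per-column state cardinality (each >= 2).
    target_states
        Cardinality ``r`` of the target.
    matrix
        ``(m, p)`` integer array, codes in ``[0, cardinality)`` per column.
    target
        Length-``m`` integer vector, codes in ``[0, target_states)``.
    """

    predictor_ids: tuple[str, ...]
    states_per_predictor: tuple[int, ...]
    target_states: int
    matrix: np.ndarray
    target: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_ids", tuple(self.predictor_ids))
        object.__setattr__(
            self, "states_per_predictor", tuple(int(c) for c in self.states_per_predictor)
        )
        matrix = np.asarray(self.matrix, dtype=np.int64)
        target = np.asarray(self.target, dtype=np.int64)
        if matrix.ndim != 2:
            raise InputError("matrix must be 2-dimensional (individuals x predictors)")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "target", target)
        p = len(self.predictor_ids)
        if len(set(self.predictor_ids)) != p:
            raise InputError("predictor_ids must be unique")
        if len(self.states_per_predictor) != p:
            raise InputError("states_per_predictor length must match predictor_ids")
        if any(c < 2 for c in self.states_per_predictor):
            raise InputError("every predictor must have at least 2 states")
        if self.target_states < 2:
            raise InputError("target must have at least 2 states")
        if matrix.shape[1] != p:
            raise InputError(
                f"matrix has {matrix.shape[1]} columns but {p} predictor ids were given"
            )
        if target.shape != (matrix.shape[0],):
            raise InputError("target length must equal the number of matrix rows")
        if matrix.size:
            lo = matrix.min(axis=0)
            hi = matrix.max(axis=0)
            cards = np.asarray(self.states_per_predictor)
            if (lo < 0).any() or (hi >= cards).any():
                bad = self.predictor_ids[int(np.argmax((lo < 0) | (hi >= cards)))]
                raise InputError(f"codes out of declared range for predictor {bad!r}")
        if target.size and (target.min() < 0 or target.max() >= self.target_states):
            raise InputError("target codes out of declared range")
        object.__setattr__(
            self, "_index", {pid: i for i, pid in enumerate(self.predictor_ids)}
        )

    #: identifier used for the target variable in derived joints; the
    #: target is the distinguished variable, not a column.
    TARGET_ID = "__target__"

    @property
    def target_id(self) -> str:
        return self.TARGET_ID

    @property
    def m(self) -> int:
        """Number of individuals (data items)."""
        return int(self.matrix.shape[0])

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_ids)

    def column_index(self, predictor_id: str) -> int:
        try:
            return self._index[predictor_id]
        except KeyError:
            raise InputError(f"unknown predictor identifier {predictor_id!r}") from None

    def columns(self, predictor_ids: Iterable[str]) -> list[int]:
        """Column indices for ``predictor_ids`` in dataset column order."""
        return sorted(self.column_index(pid) for pid in predictor_ids)


@dataclass(frozen=True)
class JointDistribution:
    """An explicit probability table over a target and a predictor subset.

    ``variable_ids`` lists the target first; ``table`` has one axis per
    variable in that order.  Population fixtures (e.g. a pure two-locus
    interaction with little marginal effect) live here, as do empirical
    relative-frequency joints derived from data.
    """

    variable_ids: tuple[str, ...]
    cardinalities: tuple[int, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))
        object.__setattr__(self, "cardinalities", tuple(int(c) for c in self.cardinalities))
        table = np.asarray(self.table, dtype=float)
        if table.shape != self.cardinalities:
            raise InputError(
                f"table shape {table.shape} does not match cardinalities {self.cardinalities}"
            )
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise InputError("variable_ids must be unique")
        if (table < -1e-12).any():
            raise InputError("probability table has negative entries")
        total = float(table.sum())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"probability table sums to {total}, not 1")
        object.__setattr__(self, "table", np.clip(table, 0.0, None))

    @property
    def target_id(self) -> str:
        return self.variable_ids[0]

    def axis_of(self, variable_id: str) -> int:
        try:
            return self.variable_ids.index(variable_id)
        except ValueError:
            raise InputError(f"unknown variable identifier {variable_id!r}") from None

    def marginal(self, keep_ids: Sequence[str]) -> "JointDistribution":
        """Marginalize down to ``keep_ids`` (given in any order; the
        returned distribution preserves this distribution's variable
        order)."""
        keep = [vid for vid in self.variable_ids if vid in set(keep_ids)]
        unknown = set(keep_ids) - set(self.variable_ids)
        if unknown:
            raise InputError(f"unknown variable identifiers {sorted(unknown)!r}")
        drop_axes = tuple(
            i for i, vid in enumerate(self.variable_ids) if vid not in keep
        )
        table = self.table.sum(axis=drop_axes) if drop_axes else self.table
        cards = tuple(self.cardinalities[self.axis_of(v)] for v in keep)
        return JointDistribution(tuple(keep), cards, table)

    def conditional(self, target_state: int, **conditions: int) -> float:
        """P(target = target_state | conditions), e.g.
        ``joint.conditional(1, Y=0)`` for a joint over (Z, X, Y)."""
        sub = self.marginal([self.target_id, *conditions])
        idx = [slice(None)] * len(sub.variable_ids)
        for vid, state in conditions.items():
            idx[sub.axis_of(vid)] = state
        slab = sub.table[tuple(idx)]
        denom = float(slab.sum())
        if denom <= 0:
            raise DegenerateInputError("conditioning event has probability 0")
        return float(slab[target_state]) / denom


@dataclass(frozen=True)
class ContingencyCounts:
    """The ``s_ijk`` count grid for one target node.

    ``counts[j, k]`` is the number of individuals whose parent-set
    instantiation has mixed-radix index ``j`` and whose target takes state
    ``k``.  ``q`` is the number of parent instantiations (1 for the empty
    parent set), ``r`` the target cardinality, ``m`` the total count.
    """

    r: int
    q: int
    counts: np.ndarray
    m: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.q, self.r):
            raise InputError(f"counts shape {counts.shape} != (q={self.q}, r={self.r})")
        if (counts < 0).any():
            raise InputError("counts must be non-negative")
        if int(counts.sum()) != self.m:
            raise InputError("counts must sum to m")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ScoredModel:
    """A candidate interaction: a predictor set with its score.

    ``fitness`` is the unified higher-is-better value all searches compare
    on (BDeu log score, or the negated MDL score); ``raw_score`` is the
    criterion's native value; ``interaction_strength`` is the set
    interaction strength of the predictor set in bits; ``origin_beam``
    names the seed predictor of the beam that produced the model.
    """

    predictor_set: frozenset[str]
    fitness: float
    raw_score: float
    interaction_strength: float
    origin_beam: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_set", frozenset(self.predictor_set))
        if not self.predictor_set:
            raise InputError("predictor_set must be non-empty")

    def sorted_members(self) -> list[str]:
        return sorted(self.predictor_set)


def parent_codes(
    dataset: GenotypeDataset, predictor_ids: Iterable[str]
) -> tuple[np.ndarray, int]:
    """Mixed-radix instantiation index for each row over the ordered
    predictor list (dataset column order, last predictor fastest).

    Returns the length-``m`` index vector and ``q``, the product of the
    parent cardinalities.  This fixed indexing convention makes every
    score bit-for-bit reproducible.
    """
    cols = dataset.columns(predictor_ids)
    if not cols:
        return np.zeros(dataset.m, dtype=np.int64), 1
    codes = np.zeros(dataset.m, dtype=np.int64)
    q = 1
    for c in cols:
        card = dataset.states_per_predictor[c]
        codes = codes * card + dataset.matrix[:, c]
        q *= card
    return codes, q


def count_table(
    dataset: GenotypeDataset, predictor_set: Iterable[str]
) -> ContingencyCounts:
    """Contingency counts of the target given a parent (predictor) set.

    The empty predictor set yields ``q = 1`` with the marginal target
    counts.  An empty dataset (``m = 0``) is allowed and returns zero
    counts.
    """
    pids = list(predictor_set)
    if len(pids) != len(set(pids)):
        raise InputError("predictor_set contains duplicates")
    codes, q = parent_codes(dataset, pids)
    r = dataset.target_states
    flat = np.bincount(codes * r + dataset.target, minlength=q * r)
    return ContingencyCounts(r=r, q=q, counts=flat.reshape(q, r), m=dataset.m)


def empirical_joint(
    dataset: GenotypeDataset, predictor_set: Iterable[str]
) -> JointDistribution:
    """Maximum-likelihood (relative frequency) joint over the target and a
    predictor subset.  No smoothing: smoothing would shift information
    gain and MDL values away from their plug-in definitions."""
    if dataset.m == 0:
        raise DegenerateInputError("cannot form an empirical joint from 0 rows")
    pids = list(predictor_set)
    cc = count_table(dataset, pids)
    cols = dataset.columns(pids)
    cards = tuple(dataset.states_per_predictor[c] for c in cols)
    # counts is (q, r) with j mixed-radix (last predictor fastest); unfold
    # j into per-predictor axes and move the target axis first.
    table = cc.counts.reshape(cards + (cc.r,)).astype(float)
    table = np.moveaxis(table, -1, 0) / float(dataset.m)
    ids = (dataset.target_id,) + tuple(dataset.predictor_ids[c] for c in cols)
    return JointDistribution(ids, (cc.r,) + cards, table)
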