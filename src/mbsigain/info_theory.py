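"""Entropy, information gain and interaction strength, in bits.

These are the statistics that drive beam growth in the interaction
search.  All logarithms are base 2.  The limit convention 0*log2(0) := 0
is used throughout, and zero-probability conditioning instantiations are
skipped.

Interaction strength (IS) of a predictor ``X`` with a set ``A`` relative
to a target ``Z`` is

    IS(Z; X, A) = IG(Z; {X} u A) - IG(Z; X) - IG(Z; A),

the increase in information gain from considering the predictors jointly
rather than separately.  IS can be negative: on a Markov chain
X -> Y -> Z it equals -IG(Z; X) <= 0, while for independent causes
(X -> Z <- Y with X independent of Y) it is always >= 0.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core_data import (
    GenotypeDataset,
    InputError,
    JointDistribution,
    empirical_joint,
)

__all__ = [
    "entropy",
    "conditional_entropy",
    "information_gain",
    "conditional_information_gain",
    "interaction_strength",
    "interaction_strength_set",
    "information_gain_data",
    "interaction_strength_data",
    "interaction_strength_set_data",
    "clamp_nonneg",
]

#: magnitude below which a negative empirical IG/IS is treated as exact zero
ZERO_FLOOR = 1e-12


def clamp_nonneg(value: float, floor: float = ZERO_FLOOR) -> float:
    """Clamp a small negative floating-point result to exactly 0.

    Empirical information gains are mathematically non-negative, but
    round-off can leave values like -3e-16; those are floored to 0 before
    any threshold comparison.  Genuinely negative values (interaction
    strengths can be negative) pass through untouched.
    """
    if -floor < value < 0.0:
        return 0.0
    return value


def _validate_pvector(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise InputError("probability vector has negative entries")
    if abs(p.sum() - 1.0) > 1e-6:
        raise InputError(f"probabilities sum to {p.sum()}, not 1")
    return p


def entropy(dist: Sequence[float]) -> float:
    """Shannon entropy -sum p_i log2 p_i of a probability vector.

    Maximized (log2 of the alternative count) at the uniform
    distribution, 0 at a degenerate one.
    """
    p = _validate_pvector(np.asarray(dist, dtype=float).ravel())
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _cond_entropy_axes(table: np.ndarray) -> float:
    """H(axis-0 variable | remaining axes) of a joint probability array."""
    p_cond = table.reshape(table.shape[0], -1).T  # (instantiations, r)
    p_inst = p_cond.sum(axis=1)
    h = 0.0
    for pj, row in zip(p_inst, p_cond):
        if pj <= 0:
            continue  # zero-probability instantiation contributes nothing
        pz = row / pj
        nz = pz[pz > 0]
        h += float(pj) * float(-(nz * np.log2(nz)).sum())
    return h


def conditional_entropy(joint: JointDistribution) -> float:
    """H(Z | conditioning set): expected entropy of the target (the
    joint's first variable) over the instantiations of the remaining
    variables, weighted by their probabilities."""
    _validate_pvector(joint.table.ravel())
    return _cond_entropy_axes(joint.table)


def information_gain(joint: JointDistribution, predictor_subset: Iterable[str]) -> float:
    """IG(Z; A) = H(Z) - H(Z | A), the expected reduction in target
    entropy from observing the predictors in ``A``.  The empty set gains
    nothing: IG(Z; {}) = 0."""
    subset = list(predictor_subset)
    z = joint.target_id
    if z in subset:
        raise InputError("predictor subset may not contain the target")
    if not subset:
        return 0.0
    sub = joint.marginal([z] + subset)
    hz = entropy(sub.marginal([z]).table)
    return hz - _cond_entropy_axes(sub.table)


def conditional_information_gain(
    joint: JointDistribution, x: str, given: Iterable[str]
) -> float:
    """IG(Z; X | Y) = sum_i IG(Z; X | y_i) P(y_i): the expected
    information gain of the target relative to ``x``, conditional on the
    variables in ``given``."""
    given = list(given)
    if x in given:
        raise InputError(f"{x!r} appears in both x and the conditioning set")
    z = joint.target_id
    if not given:
        return information_gain(joint, [x])
    sub = joint.marginal([z, x] + given)
    zx_axes = (sub.axis_of(z), sub.axis_of(x))
    cond_axes = tuple(i for i in range(len(sub.variable_ids)) if i not in zx_axes)
    # flatten conditioning axes last: table -> (r_z, r_x, n_instantiations)
    t = np.moveaxis(sub.table, zx_axes, (0, 1))
    t = t.reshape(t.shape[0], t.shape[1], -1)
    total = 0.0
    for j in range(t.shape[2]):
        block = t[:, :, j]
        pj = float(block.sum())
        if pj <= 0:
            continue
        cond = block / pj
        hz = entropy(cond.sum(axis=1))
        total += pj * (hz - _cond_entropy_axes(cond))
    return total


def interaction_strength(joint: JointDistribution, x: str, a: Iterable[str]) -> float:
    """IS(Z; X, A) = IG(Z; {X} u A) - IG(Z; X) - IG(Z; A).

    With ``a`` empty this is identically 0 (a single predictor cannot
    interact with nothing).
    """
    a = list(a)
    if x in a:
        raise InputError(f"{x!r} appears in both x and a")
    if not a:
        return 0.0
    return (
        information_gain(joint, [x] + a)
        - information_gain(joint, [x])
        - information_gain(joint, a)
    )


def interaction_strength_set(joint: JointDistribution, a: Iterable[str]) -> float:
    """Set interaction strength IS(Z; A) = IG(Z; A) - sum_{X in A} IG(Z; X).

    Collapses to 0 for a singleton.  Requires ``|A| >= 1``.
    """
    a = list(a)
    if not a:
        raise InputError("interaction strength of the empty set is undefined")
    return information_gain(joint, a) - sum(information_gain(joint, [x]) for x in a)


# ---------------------------------------------------------------------------
# Data-driven variants: plug-in estimates from relative-frequency joints.


def information_gain_data(dataset: GenotypeDataset, predictor_subset: Iterable[str]) -> float:
    subset = list(predictor_subset)
    if not subset:
        return 0.0
    return clamp_nonneg(information_gain(empirical_joint(dataset, subset), subset))


def interaction_strength_data(dataset: GenotypeDataset, x: str, a: Iterable[str]) -> float:
    a = list(a)
    if x in a:
        raise InputError(f"{x!r} appears in both x and a")
    if not a:
        return 0.0
    joint = empirical_joint(dataset, [x] + a)
    return clamp_nonneg(interaction_strength(joint, x, a))


def interaction_strength_set_data(dataset: GenotypeDataset, a: Iterable[str]) -> float:
    a = list(a)
    if not a:
        raise InputError("interaction strength of the empty set is undefined")
    joint = empirical_joint(dataset, a)
    return clamp_nonneg(interaction_strength_set(joint, a))
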