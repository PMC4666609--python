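"""Synthetic case-control generator and population fixtures.

The generator emulates the benchmark design used to evaluate epistasis
search methods: a panel of SNP genotypes (codes 0/1/2, copies of the
minor allele) under Hardy-Weinberg proportions, with a handful of
planted interaction groups whose per-group penetrances combine by a
Noisy-OR — each group is an independent potential cause of disease, so

    P(disease | genotype) = 1 - prod_k (1 - f_k(g_k)),

with ``f_k`` group k's penetrance table evaluated at that group's
genotype combination.  Individuals are drawn from the population and
banked by rejection until the case and control quotas are filled
(retrospective case-control sampling).

The default specification mirrors the published benchmark layout: 1000
predictors, 1000 cases + 1000 controls, five interaction groups of
sizes {5, 3, 3, 2, 2} (15 causative SNPs).  The exact penetrance models
of the original benchmark generator are not public, so the shipped
tables echo its printed anchors: a strong pure pair with penetrances
0.5 / 0.7, a weak pure pair at 0.07, and heterozygote-threshold
patterns of decreasing strength for the 5- and 3-locus groups.

Also provided are small population fixtures used to exercise the sign
behaviour of interaction strength: a pure two-locus interaction table
with little marginal effect, a Markov chain X -> Y -> Z (IS <= 0) and
independent causes X -> Z <- Y (IS >= 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import GenotypeDataset, InputError, JointDistribution
from .evaluation import TruthSpec

__all__ = [
    "InteractionGroup",
    "SimulationSpec",
    "SimulationError",
    "noisy_or_risk",
    "generate_dataset",
    "expected_prevalence",
    "default_spec",
    "pair_pure_interaction_table",
    "parity_interaction_table",
    "threshold_interaction_table",
    "table1_population",
    "chain_population",
    "independent_cause_population",
]

logger = logging.getLogger(__name__)

N_GENOTYPES = 3  # SNP genotype states: 0, 1, 2 copies of the minor allele


class SimulationError(RuntimeError):
    """The requested case/control quotas cannot be met."""


def pair_pure_interaction_table(p_first_het: float, p_second_het: float) -> np.ndarray:
    """3x3 penetrance table (flattened, second member fastest) for a
    pure two-locus interaction with little marginal effect: disease
    risk ``p_first_het`` when the first member is heterozygous and the
    second is not, ``p_second_het`` in the mirrored case, 0 otherwise.
    Marginally each locus shifts risk only slightly; jointly the pattern
    is strongly informative."""
    table = np.zeros((N_GENOTYPES, N_GENOTYPES))
    for g1 in range(N_GENOTYPES):
        for g2 in range(N_GENOTYPES):
            if g1 == 1 and g2 != 1:
                table[g1, g2] = p_first_het
            elif g2 == 1 and g1 != 1:
                table[g1, g2] = p_second_het
    return table.ravel()


def parity_interaction_table(size: int, penetrance: float) -> np.ndarray:
    """Penetrance table over ``3**size`` genotype combinations that
    fires (value ``penetrance``) when an odd number of group members is
    heterozygous.  A XOR-like *pure* interaction: no member subset of
    any order below ``size`` carries signal, so greedy pairwise search
    cannot grow it — the extreme regime for stress-testing."""
    shape = (N_GENOTYPES,) * size
    table = np.zeros(shape)
    for idx in np.ndindex(shape):
        if sum(1 for g in idx if g == 1) % 2 == 1:
            table[idx] = penetrance
    return table.ravel()


def threshold_interaction_table(size: int, min_het: int, penetrance: float) -> np.ndarray:
    """Penetrance table that fires when at least ``min_het`` group
    members are heterozygous.  Individual members carry modest marginal
    signal while member pairs already show interaction strength, so the
    group is discoverable by greedy beam growth — the typical regime of
    multi-locus disease models."""
    shape = (N_GENOTYPES,) * size
    table = np.zeros(shape)
    for idx in np.ndindex(shape):
        if sum(1 for g in idx if g == 1) >= min_het:
            table[idx] = penetrance
    return table.ravel()


@dataclass(frozen=True)
class InteractionGroup:
    """A planted interaction: member predictor indices, their minor
    allele frequencies, and a penetrance table over the ``3**g``
    genotype combinations (mixed-radix index, last member fastest)."""

    indices: tuple[int, ...]
    mafs: tuple[float, ...]
    penetrance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        object.__setattr__(self, "mafs", tuple(float(f) for f in self.mafs))
        pen = np.asarray(self.penetrance, dtype=float).ravel()
        object.__setattr__(self, "penetrance", pen)
        g = len(self.indices)
        if g < 1:
            raise InputError("interaction group must have at least one member")
        if len(set(self.indices)) != g:
            raise InputError("interaction group indices must be unique")
        if len(self.mafs) != g:
            raise InputError("one MAF per group member required")
        if any(not (0 < f <= 0.5) for f in self.mafs):
            raise InputError("MAFs must lie in (0, 0.5]")
        if pen.shape != (N_GENOTYPES**g,):
            raise InputError(
                f"penetrance table must have 3^{g} = {N_GENOTYPES**g} entries, got {pen.size}"
            )
        if (pen < 0).any() or (pen > 1).any():
            raise InputError("penetrance entries must lie in [0, 1]")

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated case-control study."""

    n_predictors: int
    n_cases: int
    n_controls: int
    groups: tuple[InteractionGroup, ...]
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    draw_cap: int = 10_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(
            self, "noise_maf_range", tuple(float(v) for v in self.noise_maf_range)
        )
        if self.n_predictors < 1:
            raise InputError("n_predictors must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise InputError("case and control quotas must be > 0")
        lo, hi = self.noise_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InputError("noise MAF range must satisfy 0 < low <= high <= 0.5")
        seen: set[int] = set()
        for grp in self.groups:
            for i in grp.indices:
                if not 0 <= i < self.n_predictors:
                    raise InputError(f"group index {i} out of range")
                if i in seen:
                    raise InputError(f"predictor index {i} appears in two groups")
                seen.add(i)

    @property
    def causative_indices(self) -> tuple[int, ...]:
        return tuple(sorted(i for grp in self.groups for i in grp.indices))

    def predictor_id(self, index: int) -> str:
        return f"S{index + 1}"

    def truth(self) -> TruthSpec:
        return TruthSpec(
            groups=tuple(
                frozenset(self.predictor_id(i) for i in grp.indices)
                for grp in self.groups
            )
        )


def _hw_probs(maf: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)
    per predictor; shape (len(maf), 3)."""
    p = np.asarray(maf, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)


def _group_penetrance(matrix: np.ndarray, group: InteractionGroup) -> np.ndarray:
    """Group penetrance per row of a genotype matrix."""
    codes = np.zeros(matrix.shape[0], dtype=np.int64)
    for i in group.indices:
        codes = codes * N_GENOTYPES + matrix[:, i]
    return group.penetrance[codes]


def noisy_or_risk(
    genotype: Sequence[int], groups: Sequence[InteractionGroup]
) -> float:
    """Disease probability of one individual under the Noisy-OR
    combination of the group penetrances: 1 - prod_k (1 - f_k)."""
    g = np.asarray(genotype, dtype=np.int64)[None, :]
    if g.size and ((g < 0).any() or (g >= N_GENOTYPES).any()):
        raise InputError("genotype codes must lie in {0, 1, 2}")
    survive = np.ones(1)
    for grp in groups:
        survive *= 1.0 - _group_penetrance(g, grp)
    return float(1.0 - survive[0])


def expected_prevalence(spec: SimulationSpec) -> float:
    """Analytic unconditioned disease probability: since groups are
    disjoint, E[risk] = 1 - prod_k E[1 - f_k], each expectation taken
    over the group's Hardy-Weinberg genotype distribution."""
    result = 1.0
    for grp in spec.groups:
        probs = _hw_probs(np.asarray(grp.mafs))
        weight = np.ones(1)
        for member in range(grp.size):
            weight = np.outer(weight, probs[member]).ravel()
        result *= float((weight * (1.0 - grp.penetrance)).sum())
    return 1.0 - result


def generate_dataset(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[GenotypeDataset, TruthSpec]:
    """Draw a case-control dataset from the specification.

    Genotypes follow per-predictor Hardy-Weinberg proportions (noise
    MAFs uniform in ``noise_maf_range``, causative MAFs from the group
    spec); disease status is Bernoulli in the Noisy-OR risk; rejection
    sampling banks individuals until both quotas are exactly filled.
    Fully reproducible from ``spec.seed`` (or a supplied generator).
    Rows are cases first (target 1), then controls (target 0).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    prev = expected_prevalence(spec)
    if not 0.0 < prev < 1.0:
        dead = [
            spec.predictor_id(grp.indices[0])
            for grp in spec.groups
            if grp.penetrance.max() == 0.0 or grp.penetrance.min() == 1.0
        ]
        raise SimulationError(
            f"population prevalence {prev} is degenerate; "
            f"check the group(s) anchored at {dead or 'the penetrance tables'}"
        )

    mafs = rng.uniform(*spec.noise_maf_range, size=spec.n_predictors)
    for grp in spec.groups:
        for i, f in zip(grp.indices, grp.mafs):
            mafs[i] = f
    cum = _hw_probs(mafs).cumsum(axis=1)[:, :2]  # thresholds for codes 1, 2

    need_cases, need_controls = spec.n_cases, spec.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    drawn = 0
    batch = max(1024, (spec.n_cases + spec.n_controls) // 2)
    while need_cases > 0 or need_controls > 0:
        if drawn >= spec.draw_cap:
            raise SimulationError(
                f"draw cap {spec.draw_cap} reached with {need_cases} cases and "
                f"{need_controls} controls still unfilled "
                f"(analytic prevalence {prev:.4g})"
            )
        b = min(batch, spec.draw_cap - drawn)
        u = rng.random((b, spec.n_predictors))
        genotypes = (u > cum[:, 0]).astype(np.int64) + (u > cum[:, 1])
        survive = np.ones(b)
        for grp in spec.groups:
            survive *= 1.0 - _group_penetrance(genotypes, grp)
        diseased = rng.random(b) < (1.0 - survive)
        drawn += b
        if need_cases > 0:
            picked = genotypes[diseased][:need_cases]
            case_rows.append(picked)
            need_cases -= len(picked)
        if need_controls > 0:
            picked = genotypes[~diseased][:need_controls]
            control_rows.append(picked)
            need_controls -= len(picked)
    logger.debug("simulation drew %d individuals for %d banked", drawn,
                 spec.n_cases + spec.n_controls)

    matrix = np.vstack(case_rows + control_rows)
    target = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int64), np.zeros(spec.n_controls, dtype=np.int64)]
    )
    dataset = GenotypeDataset(
        predictor_ids=tuple(spec.predictor_id(i) for i in range(spec.n_predictors)),
        states_per_predictor=(N_GENOTYPES,) * spec.n_predictors,
        target_states=2,
        matrix=matrix,
        target=target,
    )
    return dataset, spec.truth()


def default_spec(
    n_predictors: int = 1000,
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
    causative_maf: float = 0.25,
) -> SimulationSpec:
    """The benchmark-style specification: five interaction groups of
    sizes {5, 3, 3, 2, 2} (15 causative SNPs, ids S1..S15) combined by
    Noisy-OR, with penetrance tables echoing the published anchors — a
    strong pure pair (0.5 / 0.7), a weak pure pair (0.07), and
    heterozygote-threshold patterns of decreasing strength for the
    larger groups."""
    maf = (causative_maf,)

    def grp(indices: tuple[int, ...], table: np.ndarray) -> InteractionGroup:
        return InteractionGroup(indices=indices, mafs=maf * len(indices), penetrance=table)

    groups = (
        grp((0, 1, 2, 3, 4), threshold_interaction_table(5, 4, 0.5)),
        grp((5, 6, 7), threshold_interaction_table(3, 2, 0.7)),
        grp((8, 9, 10), threshold_interaction_table(3, 2, 0.5)),
        grp((11, 12), pair_pure_interaction_table(0.5, 0.7)),
        grp((13, 14), pair_pure_interaction_table(0.07, 0.07)),
    )
    return SimulationSpec(
        n_predictors=n_predictors,
        n_cases=n_cases,
        n_controls=n_controls,
        groups=groups,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Population fixtures.


def table1_population() -> JointDistribution:
    """The pure two-locus interaction population with little marginal
    effect: trinary X and Y (marginals .25/.5/.25, independent), binary
    Z with P(Z=1 | x, y) following the checkerboard pattern 0 / 0.1 /
    0.11 — jointly strongly predictive, marginally nearly silent
    (P(z1|y1) = 0.05 vs P(z1|y2) = 0.055)."""
    px = np.array([0.25, 0.5, 0.25])
    py = np.array([0.25, 0.5, 0.25])
    # rows x, cols y: P(Z=1 | x, y)
    cond = np.array(
        [
            [0.0, 0.11, 0.0],
            [0.1, 0.0, 0.1],
            [0.0, 0.11, 0.0],
        ]
    )
    pxy = np.outer(px, py)
    table = np.stack([pxy * (1 - cond), pxy * cond])  # axes (Z, X, Y)
    return JointDistribution(("Z", "X", "Y"), (2, 3, 3), table)


def chain_population(
    px: Sequence[float] = (0.4, 0.6),
    y_given_x: Sequence[Sequence[float]] = ((0.8, 0.2), (0.3, 0.7)),
    z_given_y: Sequence[Sequence[float]] = ((0.9, 0.1), (0.2, 0.8)),
) -> JointDistribution:
    """Markov chain X -> Y -> Z: X and Z are independent given Y, so
    IG(Z; X | Y) = 0 and IS(Z; X, {Y}) = -IG(Z; X) <= 0."""
    px = np.asarray(px, dtype=float)
    y_x = np.asarray(y_given_x, dtype=float)
    z_y = np.asarray(z_given_y, dtype=float)
    if y_x.shape[0] != px.size or z_y.shape[0] != y_x.shape[1]:
        raise InputError("conditional table shapes are inconsistent")
    _check_rows_normalized(y_x, "y_given_x")
    _check_rows_normalized(z_y, "z_given_y")
    # P(z, x, y) = P(x) P(y|x) P(z|y)
    table = np.einsum("x,xy,yz->zxy", px, y_x, z_y)
    return JointDistribution(("Z", "X", "Y"), table.shape, table)


def independent_cause_population(
    px: Sequence[float] = (0.7, 0.3),
    py: Sequence[float] = (0.6, 0.4),
    z_given_xy: Sequence[Sequence[float]] = ((0.05, 0.4), (0.4, 0.8)),
) -> JointDistribution:
    """Common effect X -> Z <- Y with marginally independent causes:
    the interaction strength IS(Z; X, {Y}) is guaranteed non-negative.
    ``z_given_xy[x][y]`` is P(Z=1 | x, y)."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    z_xy = np.asarray(z_given_xy, dtype=float)
    if z_xy.shape != (px.size, py.size):
        raise InputError("z_given_xy shape must be (|X|, |Y|)")
    if (z_xy < 0).any() or (z_xy > 1).any():
        raise InputError("z_given_xy entries must lie in [0, 1]")
    pxy = np.outer(px, py)
    table = np.stack([pxy * (1 - z_xy), pxy * z_xy])
    return JointDistribution(("Z", "X", "Y"), table.shape, table)


def _check_rows_normalized(table: np.ndarray, name: str) -> None:
    if (table < 0).any() or not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
        raise InputError(f"rows of {name} must be probability distributions")
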