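"""Shared fixtures: tiny hand-checkable datasets, population joints and
simulated benchmark datasets."""

from __future__ import annotations

import numpy as np
import pytest

import mbsigain as mg


@pytest.fixture
def toy_xz() -> mg.GenotypeDataset:
    """4 rows over one binary predictor X and binary target Z:
    (X, Z) = (0,0), (0,1), (1,0), (1,1) — all four cells once."""
    return mg.GenotypeDataset(
        predictor_ids=("X",),
        states_per_predictor=(2,),
        target_states=2,
        matrix=np.array([[0], [0], [1], [1]]),
        target=np.array([0, 1, 0, 1]),
    )


@pytest.fixture
def toy_copy() -> mg.GenotypeDataset:
    """Z is a deterministic copy of a uniform binary X, m = 4."""
    return mg.GenotypeDataset(
        predictor_ids=("X",),
        states_per_predictor=(2,),
        target_states=2,
        matrix=np.array([[0], [0], [1], [1]]),
        target=np.array([0, 0, 1, 1]),
    )


def random_dataset(
    rng: np.random.Generator,
    m: int = 40,
    n_predictors: int = 4,
    cards: tuple[int, ...] | None = None,
    target_states: int = 2,
) -> mg.GenotypeDataset:
    """A random discrete dataset with mildly structured target."""
    if cards is None:
        cards = tuple(int(rng.integers(2, 4)) for _ in range(n_predictors))
    matrix = np.column_stack(
        [rng.integers(0, c, size=m) for c in cards]
    )
    # target depends weakly on the first predictor so IG terms are not all 0
    bias = (matrix[:, 0] % target_states) if n_predictors else np.zeros(m, int)
    flip = rng.random(m) < 0.35
    target = np.where(flip, rng.integers(0, target_states, size=m), bias)
    return mg.GenotypeDataset(
        predictor_ids=tuple(f"P{i}" for i in range(n_predictors)),
        states_per_predictor=cards,
        target_states=target_states,
        matrix=matrix,
        target=target.astype(np.int64),
    )


def random_joint(
    rng: np.random.Generator, cards: tuple[int, ...] = (2, 2, 2)
) -> mg.JointDistribution:
    """A random strictly positive joint over (Z, X, Y, ...)."""
    table = rng.dirichlet(np.ones(int(np.prod(cards)))).reshape(cards)
    table = table + 1e-6
    table /= table.sum()
    ids = ("Z",) + tuple(f"V{i}" for i in range(len(cards) - 1))
    return mg.JointDistribution(ids, cards, table)


@pytest.fixture(scope="session")
def planted_pair_dataset() -> tuple[mg.GenotypeDataset, mg.TruthSpec]:
    """40 SNPs, 400 cases + 400 controls, one strong pure 2-SNP
    interaction (penetrances 0.5 / 0.7) at S11, S12 among noise."""
    pair = mg.InteractionGroup(
        indices=(10, 11),
        mafs=(0.25, 0.25),
        penetrance=mg.pair_pure_interaction_table(0.5, 0.7),
    )
    spec = mg.SimulationSpec(
        n_predictors=40, n_cases=400, n_controls=400, groups=(pair,), seed=3
    )
    return mg.generate_dataset(spec)


CONFOUND_PAIR = frozenset({"S6", "S7"})
CONFOUND_MARGINAL = "S10"


@pytest.fixture(scope="session")
def confound_dataset() -> tuple[mg.GenotypeDataset, mg.TruthSpec]:
    """A strong-marginal nuisance SNP alongside a planted pure pair.

    The pair (S6, S7) is a pure interaction (penetrances 0.5 / 0.7,
    little marginal effect); S10 is a common additive SNP whose effect
    combines with the pair by Noisy-OR — it raises the score of the pair
    model without interacting with it.  The planted truth is the pair.
    """
    pair = mg.InteractionGroup(
        indices=(5, 6), mafs=(0.25, 0.25),
        penetrance=mg.pair_pure_interaction_table(0.5, 0.7),
    )
    marginal = mg.InteractionGroup(
        indices=(9,), mafs=(0.5,), penetrance=np.array([0.1, 0.3, 0.5])
    )
    spec = mg.SimulationSpec(
        n_predictors=30, n_cases=1000, n_controls=1000,
        groups=(pair, marginal), seed=1,
    )
    dataset, _ = mg.generate_dataset(spec)
    truth = mg.TruthSpec(groups=(CONFOUND_PAIR,))
    return dataset, truth


@pytest.fixture
def confound_params() -> mg.SearchParams:
    """Search configuration for the confound fixture: BDeu (alpha = 4)
    with T = 0.2 — the score under which marginal absorption is most
    visible, and a threshold inside the method's useful range."""
    return mg.SearchParams(
        score=mg.ScoreParams(criterion=mg.Criterion.BDEU, alpha=4.0), T=0.2
    )


# ---------------------------------------------------------------------------
# Independent oracles used across test modules.


def naive_count_oracle(
    dataset: mg.GenotypeDataset, predictor_ids: list[str]
) -> np.ndarray:
    """Count (j, k) cells with an explicit per-row loop, mixed-radix over
    dataset column order with the last predictor fastest."""
    cols = sorted(dataset.column_index(p) for p in predictor_ids)
    cards = [dataset.states_per_predictor[c] for c in cols]
    q = int(np.prod(cards)) if cols else 1
    out = np.zeros((q, dataset.target_states), dtype=int)
    for row in range(dataset.m):
        j = 0
        for c, card in zip(cols, cards):
            j = j * card + int(dataset.matrix[row, c])
        out[j, int(dataset.target[row])] += 1
    return out


def sequential_predictive_oracle(counts: np.ndarray, a: np.ndarray) -> float:
    """Log probability of the data by feeding observations one at a time
    through the Dirichlet-multinomial posterior predictive: each cell
    (j, k) with count s contributes prod_{t<s} (a_jk + t), and each
    parent row j with total S divides by prod_{t<S} (A_j + t)."""
    total = 0.0
    for j in range(counts.shape[0]):
        row_a = float(a[j].sum())
        for k in range(counts.shape[1]):
            for t in range(int(counts[j, k])):
                total += np.log(a[j, k] + t)
        for t in range(int(counts[j].sum())):
            total -= np.log(row_a + t)
    return total


def brute_force_ig(joint: mg.JointDistribution, subset: list[str]) -> float:
    """IG(Z; subset) by explicit enumeration of the joint cells."""
    sub = joint.marginal([joint.target_id] + subset)
    t = sub.table.reshape(sub.table.shape[0], -1)
    pz = t.sum(axis=1)
    pa = t.sum(axis=0)
    ig = 0.0
    for k in range(t.shape[0]):
        for j in range(t.shape[1]):
            if t[k, j] > 0:
                ig += t[k, j] * np.log2(t[k, j] / (pz[k] * pa[j]))
    return float(ig)
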