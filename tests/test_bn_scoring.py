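"""Bayesian, BDeu and MDL scores against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

import mbsigain as mg
from mbsigain.bn_scoring import mdl_param_count
from conftest import random_dataset, sequential_predictive_oracle


def counts_of(grid, m=None) -> mg.ContingencyCounts:
    grid = np.asarray(grid)
    return mg.ContingencyCounts(
        r=grid.shape[1], q=grid.shape[0], counts=grid, m=int(grid.sum())
    )


class TestBayesianScore:
    def test_empty_data_scores_log_one(self):
        cc = counts_of([[0, 0]])
        assert mg.bayesian_log_score(cc, np.ones((1, 2))) == 0.0

    def test_two_coin_flips_uniform_prior(self):
        # sequential predictive with a = (1, 1): 1/2 * 1/3 = 1/6
        cc = counts_of([[1, 1]])
        assert mg.bayesian_log_score(cc, np.ones((1, 2))) == pytest.approx(
            np.log(1 / 6), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sequential_predictive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q, r = rng.integers(1, 4), rng.integers(2, 4)
        grid = rng.integers(0, 5, size=(q, r))
        a = rng.uniform(0.2, 3.0, size=(q, r))
        assert mg.bayesian_log_score(counts_of(grid), a) == pytest.approx(
            sequential_predictive_oracle(grid, a), abs=1e-10
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(mg.InputError):
            mg.bayesian_log_score(counts_of([[1, 1]]), np.ones((2, 2)))

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(mg.InputError):
            mg.bayesian_log_score(counts_of([[1, 1]]), np.zeros((1, 2)))


class TestBDeu:
    def test_alpha_two_equals_uniform_unit_prior(self):
        # alpha = 2, r = 2, q = 1 -> a_jk = 1, so log(1/6) for one of each
        assert mg.bdeu_log_score(counts_of([[1, 1]]), alpha=2.0) == pytest.approx(
            np.log(1 / 6), abs=1e-12
        )

    def test_zero_counts_score_zero(self):
        assert mg.bdeu_log_score(counts_of([[0, 0], [0, 0]]), alpha=4.0) == 0.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, m=50, n_predictors=2)
        perm = rng.permutation(ds.m)
        shuffled = mg.GenotypeDataset(
            ds.predictor_ids, ds.states_per_predictor, ds.target_states,
            ds.matrix[perm], ds.target[perm],
        )
        params = mg.ScoreParams(criterion=mg.Criterion.BDEU, alpha=4.0)
        assert mg.fitness(ds, ["P0", "P1"], params) == pytest.approx(
            mg.fitness(shuffled, ["P0", "P1"], params), abs=1e-12
        )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(mg.InputError):
            mg.bdeu_log_score(counts_of([[1, 1]]), alpha=0.0)


class TestMDL:
    def test_no_parent_uniform_target(self):
        # d = 1, m = 4, IG = 0: 1 * log2(4) / 2 = 1
        assert mg.mdl_score(counts_of([[2, 2]])) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_parent(self, toy_copy):
        # d = 2, m = 4, IG = 1: 2 * 1 - 4 * 1 = -2
        cc = mg.count_table(toy_copy, ["X"])
        assert mg.mdl_score(cc) == pytest.approx(-2.0, abs=1e-12)

    def test_matches_direct_double_sum(self):
        # the description length evaluated straight from its defining
        # double sum over the empirical joint
        rng = np.random.default_rng(9)
        for _ in range(50):
            q, r = int(rng.integers(1, 7)), int(rng.integers(2, 4))
            grid = rng.integers(0, 6, size=(q, r))
            if grid.sum() == 0:
                grid[0, 0] = 1
            cc = counts_of(grid)
            p = grid / grid.sum()
            pj = p.sum(axis=1)
            pk = p.sum(axis=0)
            double_sum = sum(
                p[j, k] * np.log2(p[j, k] / (pk[k] * pj[j]))
                for j in range(q)
                for k in range(r)
                if p[j, k] > 0
            )
            direct = (r - 1) * q * np.log2(cc.m) / 2 - cc.m * double_sum
            assert mg.mdl_score(cc) == pytest.approx(direct, abs=1e-9)

    def test_penalty_grows_with_parents(self):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, m=60, n_predictors=3)
        d0 = mdl_param_count(mg.count_table(ds, ["P0"]))
        d1 = mdl_param_count(mg.count_table(ds, ["P0", "P1"]))
        assert d1 > d0

    def test_empty_data_rejected(self):
        with pytest.raises(mg.DegenerateInputError):
            mg.mdl_score(counts_of([[0, 0]]))


class TestFitness:
    def test_mdl_fitness_is_negated_score(self):
        cc = counts_of([[2, 2]])
        ds = mg.GenotypeDataset(
            ("X",), (2,), 2, np.array([[0], [0], [1], [1]]),
            np.array([0, 1, 0, 1]),
        )
        assert mg.fitness(ds, [], mg.ScoreParams()) == pytest.approx(
            -mg.mdl_score(cc), abs=1e-12
        )

    @pytest.mark.parametrize("criterion", [mg.Criterion.MDL, mg.Criterion.BDEU])
    def test_deterministic_parent_beats_independent_one(self, criterion):
        rng = np.random.default_rng(6)
        m = 60
        z = rng.integers(0, 2, size=m)
        copy = z.copy()
        noise = rng.integers(0, 2, size=m)
        ds = mg.GenotypeDataset(
            ("copy", "noise"), (2, 2), 2, np.column_stack([copy, noise]), z
        )
        params = mg.ScoreParams(criterion=criterion, alpha=4.0)
        assert mg.fitness(ds, ["copy"], params) > mg.fitness(ds, ["noise"], params)

    @pytest.mark.parametrize("criterion", [mg.Criterion.MDL, mg.Criterion.BDEU])
    def test_true_pair_beats_empty_and_noise(self, planted_pair_dataset, criterion):
        dataset, truth = planted_pair_dataset
        pair = sorted(next(iter(truth.groups)))
        params = mg.ScoreParams(criterion=criterion, alpha=4.0)
        assert mg.fitness(dataset, pair, params) > mg.fitness(dataset, [], params)
        assert mg.fitness(dataset, pair, params) > mg.fitness(
            dataset, ["S1", "S2"], params
        )


class TestSinglePredictorRanking:
    def test_full_ranking_when_n_large(self, planted_pair_dataset):
        dataset, _ = planted_pair_dataset
        ranking = mg.rank_single_predictors(dataset, mg.ScoreParams(), 10_000)
        assert sorted(ranking) == sorted(dataset.predictor_ids)

    def test_strong_marginal_ranks_first(self, confound_dataset):
        dataset, _ = confound_dataset
        for criterion in (mg.Criterion.MDL, mg.Criterion.BDEU):
            params = mg.ScoreParams(criterion=criterion, alpha=4.0)
            assert mg.rank_single_predictors(dataset, params, 1) == ["S10"]

    def test_descending_fitness_order(self, planted_pair_dataset):
        dataset, _ = planted_pair_dataset
        params = mg.ScoreParams()
        ranking = mg.rank_single_predictors(dataset, params, 15)
        fits = [mg.fitness(dataset, [p], params) for p in ranking]
        assert all(a >= b - 1e-12 for a, b in zip(fits, fits[1:]))


def test_mdl_is_identity_on_random_datasets():
    """Interaction strength equals the MDL-difference form
    (mdl(X) + mdl(A) - mdl(XA)) / m + C with the parameter-count
    constant C — the identity that lets the search rank candidates by
    score differences."""
    rng = np.random.default_rng(42)
    for _ in range(40):
        ds = random_dataset(rng, m=int(rng.integers(20, 60)), n_predictors=3)
        x, a = "P0", ["P1", "P2"]
        joint = mg.empirical_joint(ds, [x] + a)
        is_val = mg.interaction_strength(joint, x, a)
        cx = mg.count_table(ds, [x])
        ca = mg.count_table(ds, a)
        cxa = mg.count_table(ds, [x] + a)
        delta_d = (
            mdl_param_count(cx) + mdl_param_count(ca) - mdl_param_count(cxa)
        )
        c = -delta_d * np.log2(ds.m) / (2 * ds.m)
        via_mdl = (
            mg.mdl_score(cx) + mg.mdl_score(ca) - mg.mdl_score(cxa)
        ) / ds.m + c
        assert is_val == pytest.approx(via_mdl, abs=1e-9)
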