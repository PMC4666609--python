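"""Entropy, information gain and interaction strength properties."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbsigain as mg
from conftest import brute_force_ig, random_joint


def _h2(p: float) -> float:
    """Binary entropy in bits."""
    if p in (0.0, 1.0):
        return 0.0
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


class TestEntropy:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            ((0.5, 0.5), 1.0),
            ((1.0, 0.0), 0.0),
            ((0.25, 0.5, 0.25), 1.5),
            ((0.25, 0.25, 0.25, 0.25), 2.0),
        ],
    )
    def test_known_values(self, dist, expected):
        assert mg.entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(mg.InputError):
            mg.entropy([0.7, -0.1, 0.4])
        with pytest.raises(mg.InputError):
            mg.entropy([0.7, 0.7])


class TestConditionalEntropy:
    def test_independence_leaves_entropy_unchanged(self):
        pz, px = np.array([0.3, 0.7]), np.array([0.2, 0.5, 0.3])
        joint = mg.JointDistribution(("Z", "X"), (2, 3), np.outer(pz, px))
        assert mg.conditional_entropy(joint) == pytest.approx(
            mg.entropy(pz), abs=1e-12
        )

    def test_functional_dependence_gives_zero(self):
        table = np.array([[0.5, 0.0], [0.0, 0.5]])
        joint = mg.JointDistribution(("Z", "X"), (2, 2), table)
        assert mg.conditional_entropy(joint) == pytest.approx(0.0, abs=1e-12)

    def test_pure_interaction_population_value(self):
        # H(Z|Y) = .25 H(.05) + .5 H(.055) + .25 H(.05) on the two-locus
        # little-marginal-effect population
        joint = mg.table1_population().marginal(["Z", "Y"])
        expected = 0.25 * _h2(0.05) + 0.5 * _h2(0.055) + 0.25 * _h2(0.05)
        assert mg.conditional_entropy(joint) == pytest.approx(expected, abs=1e-12)


class TestInformationGain:
    def test_empty_subset_gains_nothing(self):
        rng = np.random.default_rng(0)
        assert mg.information_gain(random_joint(rng), []) == 0.0

    def test_copy_gains_full_entropy(self):
        table = np.array([[0.5, 0.0], [0.0, 0.5]])
        joint = mg.JointDistribution(("Z", "X"), (2, 2), table)
        assert mg.information_gain(joint, ["X"]) == pytest.approx(1.0, abs=1e-12)

    def test_marginal_gain_is_small_on_pure_interaction(self):
        joint = mg.table1_population()
        ig_y = mg.information_gain(joint, ["Y"])
        assert ig_y == pytest.approx(brute_force_ig(joint, ["Y"]), abs=1e-12)
        assert 0 < ig_y < 1e-3  # little marginal effect
        # jointly the pair is far more informative than marginally
        assert mg.information_gain(joint, ["X", "Y"]) > 100 * ig_y

    def test_unknown_identifier_rejected(self):
        with pytest.raises(mg.InputError):
            mg.information_gain(mg.table1_population(), ["W"])


class TestConditionalInformationGain:
    def test_chain_population_conditionally_independent(self):
        chain = mg.chain_population()
        assert mg.conditional_information_gain(chain, "X", ["Y"]) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_empty_conditioning_reduces_to_information_gain(self):
        rng = np.random.default_rng(1)
        joint = random_joint(rng, (2, 3, 2))
        assert mg.conditional_information_gain(joint, "V0", []) == pytest.approx(
            mg.information_gain(joint, ["V0"]), abs=1e-12
        )

    def test_overlap_rejected(self):
        with pytest.raises(mg.InputError):
            mg.conditional_information_gain(mg.table1_population(), "X", ["X"])


class TestInteractionStrength:
    def test_empty_set_gives_zero(self):
        assert mg.interaction_strength(mg.table1_population(), "X", []) == 0.0

    def test_pure_interaction_dwarfs_marginal_gains(self):
        joint = mg.table1_population()
        is_xy = mg.interaction_strength(joint, "X", ["Y"])
        ig_x = mg.information_gain(joint, ["X"])
        ig_y = mg.information_gain(joint, ["Y"])
        oracle = (
            brute_force_ig(joint, ["X", "Y"])
            - brute_force_ig(joint, ["X"])
            - brute_force_ig(joint, ["Y"])
        )
        assert is_xy == pytest.approx(oracle, abs=1e-12)
        assert is_xy > 100 * (ig_x + ig_y)

    def test_chain_population_equals_minus_marginal_gain(self):
        chain = mg.chain_population()
        is_x = mg.interaction_strength(chain, "X", ["Y"])
        assert is_x == pytest.approx(-mg.information_gain(chain, ["X"]), abs=1e-10)
        assert is_x <= 0

    def test_set_form_collapses_for_singleton(self):
        assert mg.interaction_strength_set(mg.table1_population(), ["X"]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_set_form_matches_pair_form(self):
        rng = np.random.default_rng(2)
        joint = random_joint(rng, (2, 3, 3))
        assert mg.interaction_strength_set(joint, ["V0", "V1"]) == pytest.approx(
            mg.interaction_strength(joint, "V0", ["V1"]), abs=1e-12
        )

    def test_independent_causes_nonnegative(self):
        joint = mg.independent_cause_population()
        assert mg.interaction_strength(joint, "X", ["Y"]) >= -1e-12

    def test_empty_set_input_rejected(self):
        with pytest.raises(mg.InputError):
            mg.interaction_strength_set(mg.table1_population(), [])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_ig_properties_on_random_joints(seed):
    """Non-negativity, symmetry, chain rule and monotonicity of IG on
    random strictly positive small joints."""
    rng = np.random.default_rng(seed)
    joint = random_joint(rng, (2, 3, 2))
    ig_x = mg.information_gain(joint, ["V0"])
    ig_y = mg.information_gain(joint, ["V1"])
    ig_xy = mg.information_gain(joint, ["V0", "V1"])
    # non-negativity
    assert min(ig_x, ig_y, ig_xy) >= -1e-12
    # symmetry IG(Z;X) = IG(X;Z): swap axes so V0 is the target
    swapped = mg.JointDistribution(
        ("V0", "Z", "V1"),
        (joint.cardinalities[1], joint.cardinalities[0], joint.cardinalities[2]),
        np.swapaxes(joint.table, 0, 1),
    )
    assert ig_x == pytest.approx(mg.information_gain(swapped, ["Z"]), abs=1e-10)
    # chain rule IG(Z;{X,Y}) = IG(Z;X|Y) + IG(Z;Y)
    assert ig_xy == pytest.approx(
        mg.conditional_information_gain(joint, "V0", ["V1"]) + ig_y, abs=1e-10
    )
    # monotonicity
    assert ig_xy >= ig_y - 1e-10


def test_ig_zero_iff_independent():
    """IG vanishes exactly on a product joint and is strictly positive
    on a dependent one."""
    pz, px = np.array([0.4, 0.6]), np.array([0.3, 0.2, 0.5])
    product = mg.JointDistribution(("Z", "X"), (2, 3), np.outer(pz, px))
    assert mg.information_gain(product, ["X"]) == pytest.approx(0.0, abs=1e-12)
    dependent = mg.JointDistribution(
        ("Z", "X"), (2, 2), np.array([[0.4, 0.1], [0.1, 0.4]])
    )
    assert mg.information_gain(dependent, ["X"]) > 0.1


def test_data_driven_variants_compose_empirical_joint(planted_pair_dataset):
    dataset, truth = planted_pair_dataset
    a, b = sorted(next(iter(truth.groups)))
    joint = mg.empirical_joint(dataset, [a, b])
    assert mg.information_gain_data(dataset, [a, b]) == pytest.approx(
        mg.information_gain(joint, [a, b]), abs=1e-12
    )
    assert mg.interaction_strength_data(dataset, a, [b]) == pytest.approx(
        mg.interaction_strength(joint, a, [b]), abs=1e-12
    )


def test_clamp_floors_tiny_negatives_only():
    assert mg.clamp_nonneg(-1e-13) == 0.0
    assert mg.clamp_nonneg(-1e-3) == -1e-3
    assert mg.clamp_nonneg(0.2) == 0.2
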