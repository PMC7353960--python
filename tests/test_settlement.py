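import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypovet import (
    HypothesisSpec,
    Landscape,
    conspecific_attraction_spec,
    generate_landscape,
    habitat_preference_spec,
    null_spec,
    proportion_habitat_a,
    simulate_settlement,
    weights_conspecific_attraction,
    weights_habitat_preference,
    weights_null,
)

TWO_BY_TWO = Landscape(np.array([["A", "B"], ["B", "B"]]))


class TestSpecValidation:
    def test_omega_below_one_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            habitat_preference_spec(0.5)

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError, match="s >= 0"):
            conspecific_attraction_spec(-1)

    def test_custom_without_rule_rejected(self):
        with pytest.raises(ValueError, match="weight_rule"):
            HypothesisSpec(name="x", family="custom")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            HypothesisSpec(name="x", family="density_dependence")


class TestNullWeights:
    def test_uniform_on_empty_landscape(self):
        assert weights_null(TWO_BY_TWO, set()).tolist() == [1, 1, 1, 1]

    def test_occupied_cells_excluded(self):
        w = weights_null(TWO_BY_TWO, {(0, 0)})
        assert w.tolist() == [1, 1, 1]

    def test_full_landscape_rejected(self, abb_landscape):
        with pytest.raises(ValueError, match="full"):
            weights_null(abb_landscape, {(0, 0), (0, 1), (0, 2)})


class TestHabitatPreferenceWeights:
    def test_odds_weight_on_a_cells(self, abb_landscape):
        w = weights_habitat_preference(abb_landscape, set(), omega=2)
        assert w.tolist() == [2, 1, 1]
        assert w[0] / w.sum() == 0.5  # normalized selection probability of A

    def test_omega_one_is_null(self, abb_landscape):
        w = weights_habitat_preference(abb_landscape, set(), omega=1)
        assert w.tolist() == weights_null(abb_landscape, set()).tolist()

    def test_occupied_a_cell_excluded(self, abb_landscape):
        w = weights_habitat_preference(abb_landscape, {(0, 0)}, omega=2)
        assert w.tolist() == [1, 1]

    def test_omega_below_one_rejected(self, abb_landscape):
        with pytest.raises(ValueError, match="omega"):
            weights_habitat_preference(abb_landscape, set(), omega=0.9)


class TestConspecificAttractionWeights:
    def test_first_settler_uniform(self, abb_landscape):
        w = weights_conspecific_attraction(abb_landscape, set(), s=3.0)
        assert w.tolist() == [1, 1, 1]

    def test_s_zero_is_null(self, abb_landscape):
        w = weights_conspecific_attraction(abb_landscape, {(0, 0)}, s=0.0)
        assert w.tolist() == [1, 1]

    def test_exponential_decay_with_distance(self, abb_landscape):
        w = weights_conspecific_attraction(abb_landscape, {(0, 0)}, s=1.0)
        assert w == pytest.approx([math.exp(-1), math.exp(-2)])

    def test_nearest_occupied_governs(self):
        land = Landscape(np.array([["B", "B", "B", "B"]]))
        w = weights_conspecific_attraction(land, {(0, 0), (0, 3)}, s=2.0)
        # free cells (0,1), (0,2) are both at distance 1 from their nearest settler
        assert w == pytest.approx([math.exp(-2), math.exp(-2)])

    def test_negative_s_rejected(self, abb_landscape):
        with pytest.raises(ValueError, match="s must be"):
            weights_conspecific_attraction(abb_landscape, set(), s=-0.1)


class TestSimulateSettlement:
    def test_full_occupancy_conserves_habitats(self, abb_landscape):
        result = simulate_settlement(abb_landscape, null_spec(), 3, seed=5)
        assert sorted(result.settled) == [(0, 0), (0, 1), (0, 2)]
        assert sorted(result.habitats) == ["A", "B", "B"]

    def test_same_seed_reproduces_identical_result(self):
        land = generate_landscape(8, 8, 0.5, "random", seed=2)
        spec = conspecific_attraction_spec(1.5)
        a = simulate_settlement(land, spec, 20, seed=77)
        b = simulate_settlement(land, spec, 20, seed=77)
        assert a == b

    def test_too_many_agents_rejected(self, abb_landscape):
        with pytest.raises(ValueError, match="n_agents"):
            simulate_settlement(abb_landscape, null_spec(), 4, seed=0)

    def test_habitats_match_landscape_labels(self):
        land = generate_landscape(6, 6, 0.4, "random", seed=11)
        result = simulate_settlement(land, habitat_preference_spec(4), 15, seed=3)
        for (r, c), h in zip(result.settled, result.habitats):
            assert land.habitat[r, c] == h

    @pytest.mark.parametrize("make_null_limit", [
        lambda: habitat_preference_spec(1.0),
        lambda: conspecific_attraction_spec(0.0),
    ])
    def test_null_limit_reproduces_null_sequences(self, make_null_limit):
        """omega=1 and s=0 are parameter-forced null models: identical
        settlement sequences under shared seeds."""
        land = generate_landscape(10, 10, 0.5, "random", seed=4)
        for seed in range(5):
            ref = simulate_settlement(land, null_spec(), 30, seed=seed)
            res = simulate_settlement(land, make_null_limit(), 30, seed=seed)
            assert res.settled == ref.settled


class TestCustomWeightRule:
    def test_uniform_custom_rule_matches_null_sequences(self):
        land = generate_landscape(5, 5, 0.5, "random", seed=0)
        rule = lambda landscape, occupied, params: np.ones(
            landscape.n_cells - len(occupied)
        )
        spec = HypothesisSpec(name="flat", family="custom", weight_rule=rule)
        for seed in (0, 1, 2):
            assert (
                simulate_settlement(land, spec, 10, seed=seed).settled
                == simulate_settlement(land, null_spec(), 10, seed=seed).settled
            )

    def test_wrong_length_rule_rejected(self, abb_landscape):
        spec = HypothesisSpec(
            name="short", family="custom",
            weight_rule=lambda l, o, p: np.ones(1),
        )
        with pytest.raises(ValueError, match="short"):
            simulate_settlement(abb_landscape, spec, 2, seed=0)

    def test_all_zero_rule_rejected(self, abb_landscape):
        spec = HypothesisSpec(
            name="zeros", family="custom",
            weight_rule=lambda l, o, p: np.zeros(3 - len(o)),
        )
        with pytest.raises(ValueError, match="zeros"):
            simulate_settlement(abb_landscape, spec, 1, seed=0)

    def test_negative_weight_rule_rejected(self, abb_landscape):
        spec = HypothesisSpec(
            name="neg", family="custom",
            weight_rule=lambda l, o, p: np.full(3 - len(o), -1.0),
        )
        with pytest.raises(ValueError, match="neg"):
            simulate_settlement(abb_landscape, spec, 1, seed=0)


class TestProportionHabitatA:
    def test_full_occupancy_forced_value(self, abb_landscape):
        result = simulate_settlement(abb_landscape, null_spec(), 3, seed=1)
        assert proportion_habitat_a(result, abb_landscape) == pytest.approx(1 / 3)

    def test_direct_count(self):
        land = generate_landscape(2, 2, 0.5, "blocked", seed=0)
        result = simulate_settlement(land, null_spec(), 4, seed=0)
        assert proportion_habitat_a(result, land) == 0.5

    def test_wrong_landscape_rejected(self, abb_landscape):
        other = generate_landscape(3, 3, 0.5, "random", seed=0)
        result = simulate_settlement(abb_landscape, null_spec(), 2, seed=0)
        with pytest.raises(ValueError, match="landscape"):
            proportion_habitat_a(result, other)


@pytest.mark.parametrize(
    "family,kwargs",
    [
        ("null", {}),
        ("habitat_preference", {"omega": 3.0}),
        ("conspecific_attraction", {"s": 1.0}),
    ],
)
def test_sequence_distribution_matches_exact_enumeration(
    family, kwargs, square_landscape, sequence_oracle, sequence_empirics
):
    """Empirical settlement-sequence frequencies match brute-force
    enumerated probabilities (total variation distance < 0.01)."""
    if family == "null":
        spec = null_spec()
    elif family == "habitat_preference":
        spec = habitat_preference_spec(kwargs["omega"])
    else:
        spec = conspecific_attraction_spec(kwargs["s"])
    exact = sequence_oracle(
        [["A", "A"], ["B", "B"]], family, n_agents=2, **kwargs
    )
    assert sum(exact.values()) == pytest.approx(1.0)
    emp = sequence_empirics(square_landscape, spec, n_agents=2, n_sims=100_000)
    tv = 0.5 * sum(
        abs(exact.get(seq, 0.0) - emp.get(seq, 0.0)) for seq in set(exact) | set(emp)
    )
    assert tv < 0.01


def test_two_step_habitat_preference_probability(sequence_oracle):
    """On [A,B,B] with omega=2 and two settlers, the enumerated probability
    that the A cell is settled is 5/6 (1/2 on the first draw, else 2/3 on
    the second)."""
    seq_probs = sequence_oracle(
        [["A", "B", "B"]], "habitat_preference", n_agents=2, omega=2
    )
    p_a = sum(p for seq, p in seq_probs.items() if (0, 0) in seq)
    assert p_a == pytest.approx(5 / 6)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    n_rows=st.integers(2, 6),
    n_cols=st.integers(2, 6),
    n_agents=st.integers(1, 8),
    seed=st.integers(0, 2**31 - 1),
    spec=st.sampled_from(
        [null_spec(), habitat_preference_spec(5), conspecific_attraction_spec(2)]
    ),
)
def test_settlement_conservation_properties(n_rows, n_cols, n_agents, seed, spec):
    """Every result settles exactly n_agents distinct cells inside the grid."""
    n_agents = min(n_agents, n_rows * n_cols)
    land = generate_landscape(n_rows, n_cols, 0.5, "random", seed=seed)
    result = simulate_settlement(land, spec, n_agents, seed=seed)
    assert result.n_agents == n_agents
    assert len(set(result.settled)) == n_agents
    assert all(0 <= r < n_rows and 0 <= c < n_cols for r, c in result.settled)
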