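"""The tournament tree: coin-flip neuron, local competitions, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmsim.core import (
    CompetitionFunction,
    ContractViolation,
    EMPTY_GIST,
    make_submission_chunk,
    null_chunk,
)
from ctmsim.uptree import (
    assign_leaves,
    coin_flip_select,
    exact_win_probabilities,
    local_compete,
    monte_carlo_win_frequencies,
    run_competition,
)

F_INT = CompetitionFunction.linear(0.0)  # f = intensity


def chunks_from_weights(weights, t=0):
    return [make_submission_chunk(i, t, EMPTY_GIST, w)
            for i, w in enumerate(weights)]


class TestCoinFlipNeuron:
    def test_zero_vs_positive_forces_the_positive_side(self, rng):
        assert all(coin_flip_select(5.0, 0.0, rng) == 0 for _ in range(100))
        assert all(coin_flip_select(0.0, 5.0, rng) == 1 for _ in range(100))

    def test_consumes_exactly_one_draw_regardless_of_inputs(self):
        r1 = np.random.default_rng(0)
        r2 = np.random.default_rng(0)
        coin_flip_select(5.0, 0.0, r1)
        coin_flip_select(0.0, 0.0, r2)
        assert r1.random() == r2.random()

    def test_unbalanced_frequency_matches_a_over_a_plus_b(self, rng):
        n = 20_000
        firsts = sum(coin_flip_select(1.0, 3.0, rng) == 0 for _ in range(n))
        p = 0.25
        assert abs(firsts / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    @pytest.mark.parametrize("a,b", [(-1.0, 0.0), (0.0, float("nan"))])
    def test_invalid_inputs_rejected(self, a, b, rng):
        with pytest.raises(ContractViolation):
            coin_flip_select(a, b, rng)


class TestLocalCompete:
    def test_merged_aggregates_are_sums_and_identity_is_a_winner(self, rng):
        left = make_submission_chunk(0, 0, EMPTY_GIST, 2.0)
        right = make_submission_chunk(1, 0, EMPTY_GIST, -1.0)
        merged = local_compete(left, right, F_INT, rng)
        assert merged.intensity == pytest.approx(3.0)
        assert merged.mood == pytest.approx(1.0)
        assert merged.identity() in (left.identity(), right.identity())

    def test_positive_chunk_always_beats_the_null_chunk(self, rng):
        left = make_submission_chunk(0, 0, EMPTY_GIST, 1.0)
        for _ in range(50):
            merged = local_compete(left, null_chunk(1, 0), F_INT, rng)
            assert merged.identity() == left.identity()
            assert merged.intensity == left.intensity

    def test_two_nulls_merge_to_zero_aggregates(self, rng):
        merged = local_compete(null_chunk(0, 0), null_chunk(1, 0), F_INT, rng)
        assert merged.intensity == 0.0 and merged.mood == 0.0

    def test_win_frequency_proportional_to_f(self, rng):
        left = make_submission_chunk(0, 0, EMPTY_GIST, 2.0)
        right = make_submission_chunk(1, 0, EMPTY_GIST, -1.0)
        n = 30_000
        wins = sum(
            local_compete(left, right, F_INT, rng).address == 0 for _ in range(n)
        )
        assert abs(wins / n - 2 / 3) < 3 * np.sqrt((2 / 3) * (1 / 3) / n)


class TestRunCompetition:
    def test_wrong_submission_count_rejected(self, rng):
        with pytest.raises(ContractViolation):
            run_competition([], F_INT, rng)

    def test_root_mood_is_sum_of_all_moods_regardless_of_winner(self, rng):
        # moods (1, -2, 0.5, 0.5) cancel exactly
        chunks = chunks_from_weights([1.0, -2.0, 0.5, 0.5])
        for _ in range(20):
            root = run_competition(chunks, F_INT, rng)
            assert root.mood == pytest.approx(0.0)
            assert root.intensity == pytest.approx(4.0)

    @given(
        weights=st.lists(
            st.floats(min_value=-10, max_value=10,
                      allow_nan=False, allow_infinity=False),
            min_size=1, max_size=16,
        ),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_conservation_and_identity_preservation(self, weights, seed):
        """Root intensity/mood equal the leaf sums exactly and the root's
        identity quadruple equals some submitted chunk's."""
        rng = np.random.default_rng(seed)
        chunks = chunks_from_weights(weights)
        root = run_competition(chunks, F_INT, rng)
        assert root.intensity == pytest.approx(
            sum(abs(w) for w in weights), abs=1e-9)
        assert root.mood == pytest.approx(sum(weights), abs=1e-9)
        if root.address < len(weights):
            assert root.identity() in [ch.identity() for ch in chunks]
        else:
            # a padded null leaf can only win an all-zero competition
            assert root.gist.is_empty and root.weight == 0.0
            assert all(w == 0.0 for w in weights)


class TestExactOracle:
    def test_additive_f_gives_proportional_share(self):
        fv = [3, 1, 2, 2, 0, 4, 1, 3]
        table = exact_win_probabilities(chunks_from_weights(fv), F_INT)
        expected = np.array(fv) / sum(fv)
        assert np.max(np.abs(table.probabilities - expected)) < 1e-12

    def test_all_zero_leaves_win_uniformly(self):
        table = exact_win_probabilities(chunks_from_weights([0.0] * 4), F_INT)
        assert np.allclose(table.probabilities, 0.25, atol=1e-15)

    def test_padding_leaves_theorem_intact_for_non_power_of_two(self):
        fv = [3.0, 1.0, 2.0]  # padded to 4 leaves with a null
        table = exact_win_probabilities(chunks_from_weights(fv), F_INT)
        assert np.allclose(table.probabilities[:3], np.array(fv) / 6.0,
                           atol=1e-12)
        assert table.probabilities[3] == 0.0

    def test_positive_f_implies_positive_win_probability(self):
        # even a tiny chunk has some chance of reaching STM
        fv = [1e-6, 100.0, 100.0, 100.0]
        table = exact_win_probabilities(chunks_from_weights(fv), F_INT)
        assert table.probabilities[0] > 0

    def test_probabilities_sum_to_one_for_non_additive_f(self):
        f_abs_mood = CompetitionFunction.custom(lambda ch: abs(ch.mood))
        chunks = chunks_from_weights([1.0, -1.0, 2.0, -2.0])
        table = exact_win_probabilities(chunks, f_abs_mood)
        assert abs(table.probabilities.sum() - 1.0) < 1e-12

    def test_oracle_matches_generic_simulation_for_nonadditive_f(self):
        """The DP oracle and the chunk-level tournament agree for |mood|,
        where no closed form applies."""
        f_abs_mood = CompetitionFunction.custom(lambda ch: abs(ch.mood))
        chunks = chunks_from_weights([1.0, -1.0, 2.0, -2.0])
        table = exact_win_probabilities(chunks, f_abs_mood)
        rng = np.random.default_rng(77)
        runs = 40_000
        counts = np.zeros(4)
        for _ in range(runs):
            counts[run_competition(chunks, f_abs_mood, rng).address] += 1
        freqs = counts / runs
        for i in range(4):
            p = table.probabilities[i]
            se = np.sqrt(p * (1 - p) / runs)
            assert abs(freqs[i] - p) < 4 * se + 1e-12


class TestLeafAssignment:
    def test_identity_permutation_by_default(self):
        tree = assign_leaves(4)
        assert tree.permutation == (0, 1, 2, 3)

    def test_non_bijective_permutation_rejected(self):
        with pytest.raises(ContractViolation):
            assign_leaves(4, [0, 1, 1, 3])

    def test_permutation_invariance_for_additive_f(self):
        fv = [3, 1, 2, 2, 0, 4, 1, 3]
        chunks = chunks_from_weights(fv)
        base = exact_win_probabilities(chunks, F_INT).probabilities
        rng = np.random.default_rng(5)
        for _ in range(10):
            perm = rng.permutation(8)
            permuted = [chunks[p] for p in perm]
            table = exact_win_probabilities(permuted, F_INT).probabilities
            # map leaf-slot probabilities back to processor addresses
            by_addr = np.empty(8)
            by_addr[perm] = table
            assert np.max(np.abs(by_addr - base)) < 1e-12

    def test_permutation_changes_outcome_for_nonadditive_f(self):
        f_abs_mood = CompetitionFunction.custom(lambda ch: abs(ch.mood))
        chunks = chunks_from_weights([1.0, -1.0, 2.0, -2.0])
        base = exact_win_probabilities(chunks, f_abs_mood).probabilities
        swapped = [chunks[i] for i in (0, 2, 1, 3)]
        table = exact_win_probabilities(swapped, f_abs_mood).probabilities
        by_addr = np.empty(4)
        by_addr[[0, 2, 1, 3]] = table
        assert np.max(np.abs(by_addr - base)) > 1e-6


class TestMonteCarloFastPath:
    def test_fast_path_agrees_with_generic_tournament(self):
        """The vectorised additive-f simulator and the chunk-level
        tournament target the same distribution."""
        fv = [3.0, 1.0, 2.0, 2.0]
        chunks = chunks_from_weights(fv)
        runs = 20_000
        fast = monte_carlo_win_frequencies(fv, runs, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        counts = np.zeros(4)
        for _ in range(runs):
            counts[run_competition(chunks, F_INT, rng).address] += 1
        slow = counts / runs
        expected = np.array(fv) / sum(fv)
        for freqs in (fast, slow):
            for i, p in enumerate(expected):
                se = np.sqrt(p * (1 - p) / runs)
                assert abs(freqs[i] - p) < 4 * se

    def test_rejects_negative_f_values(self, rng):
        with pytest.raises(ContractViolation):
            monte_carlo_win_frequencies([1.0, -2.0], 10, rng)
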