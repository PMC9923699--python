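"""Scrambling algorithms and word-order metrics against brute-force oracles."""

import itertools
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scramblex as sx
from scramblex.scramble import (
    LabeledSentence,
    inversion_distance,
    local_swap_scramble,
    max_separation_order,
    min_pmi_scramble,
    words_moved,
)

# ---------------------------------------------------------------------------
# independent oracles


def bfs_swap_distance(start: tuple, goal: tuple) -> int:
    """Shortest path over adjacent transpositions, breadth-first."""
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, d = frontier.popleft()
        for i in range(len(state) - 1):
            nxt = list(state)
            nxt[i], nxt[i + 1] = nxt[i + 1], nxt[i]
            nxt = tuple(nxt)
            if nxt == goal:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    raise AssertionError("unreachable permutation")


def separation_sum(order: list, original: list) -> int:
    """Sum of position distances between originally adjacent items."""
    pos = {item: p for p, item in enumerate(order)}
    return sum(
        abs(pos[a] - pos[b]) for a, b in zip(original, original[1:])
    )


def lis_length(perm) -> int:
    best: list[int] = []
    import bisect

    for v in perm:
        i = bisect.bisect_left(best, v)
        if i == len(best):
            best.append(v)
        else:
            best[i] = v
    return len(best)


# ---------------------------------------------------------------------------
# inversion distance


class TestInversionDistance:
    def test_identity_is_zero(self):
        assert inversion_distance([3, 1, 2], [3, 1, 2]) == 0

    def test_full_reversal_of_four(self):
        assert inversion_distance([0, 1, 2, 3], [3, 2, 1, 0]) == 6

    def test_printed_intact_scr7_pair_is_seven(self):
        intact = (
            "on their last day they were overwhelmed by farewell "
            "messages and gifts"
        ).split()
        scr7 = (
            "their last on they overwhelmed were day farewell by "
            "messages and gifts"
        ).split()
        index = {w: i for i, w in enumerate(intact)}
        assert inversion_distance(
            list(range(12)), [index[w] for w in scr7]
        ) == 7

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_bfs_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            a = tuple(rng.permutation(n).tolist())
            b = tuple(rng.permutation(n).tolist())
            assert inversion_distance(a, b) == bfs_swap_distance(a, b)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            perms = [tuple(rng.permutation(7).tolist()) for _ in range(3)]
            a, b, c = perms
            assert inversion_distance(a, b) == inversion_distance(b, a)
            assert inversion_distance(a, c) <= (
                inversion_distance(a, b) + inversion_distance(b, c)
            )

    def test_different_index_sets_rejected(self):
        with pytest.raises(ValueError):
            inversion_distance([0, 1], [1, 2])


# ---------------------------------------------------------------------------
# words moved


class TestWordsMoved:
    def test_printed_examples(self):
        original = "the dog chased the cat".split()
        assert words_moved(original, "dog the cat chased the".split()) == 2
        assert words_moved(original, "the chased the cat dog".split()) == 1

    def test_printed_scr7_pair_moves_four(self):
        intact = (
            "on their last day they were overwhelmed by farewell "
            "messages and gifts"
        ).split()
        scr7 = (
            "their last on they overwhelmed were day farewell by "
            "messages and gifts"
        ).split()
        assert words_moved(intact, scr7) == 4
        # cross-check with the longest-increasing-subsequence oracle
        index = {w: i for i, w in enumerate(intact)}
        perm = [index[w] for w in scr7]
        assert words_moved(intact, scr7) == 12 - lis_length(perm)

    def test_identity_moves_nothing(self):
        assert words_moved(["a", "b", "c"], ["a", "b", "c"]) == 0

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            words_moved(["a", "b"], ["a", "a"])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.permutations(list(range(9))))
    def test_never_exceeds_inversion_distance(self, perm):
        tokens = [f"w{i}" for i in range(9)]
        scrambled = [tokens[i] for i in perm]
        moved = words_moved(tokens, scrambled)
        assert moved <= inversion_distance(list(range(9)), list(perm))
        assert moved == 9 - lis_length(perm)


# ---------------------------------------------------------------------------
# local swaps


class TestLocalSwapScramble:
    def test_zero_swaps_is_identity(self):
        rec = local_swap_scramble(list("abcd"), 0, seed=1)
        assert rec.permutation == (0, 1, 2, 3)
        assert rec.realized_inversion_distance == 0

    def test_one_swap_moves_one_word(self):
        rec = local_swap_scramble(list("abcdefghijkl"), 1, seed=2)
        assert rec.realized_inversion_distance == 1
        assert words_moved(rec.original_tokens, rec.scrambled_tokens) == 1

    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_realized_distance_equals_request(self, k):
        tokens = [f"w{i}" for i in range(12)]
        rec = local_swap_scramble(tokens, k, seed=k)
        realized = inversion_distance(
            list(range(12)), list(rec.permutation)
        )
        assert realized == k == rec.realized_inversion_distance

    def test_reproducible_under_seed(self):
        tokens = [f"w{i}" for i in range(12)]
        a = local_swap_scramble(tokens, 5, seed=77)
        b = local_swap_scramble(tokens, 5, seed=77)
        assert a.permutation == b.permutation

    def test_k_beyond_max_distance_rejected(self):
        with pytest.raises(ValueError):
            local_swap_scramble(["a", "b", "c"], 4, seed=0)

    def test_retries_exhausted_names_seed(self):
        tokens = [f"w{i}" for i in range(12)]
        with pytest.raises(RuntimeError, match="seed=123"):
            local_swap_scramble(tokens, 7, seed=123, max_retries=1)


# ---------------------------------------------------------------------------
# maximal separation / low-PMI scramble


class TestMaxSeparationOrder:
    def test_printed_content_word_example(self):
        content = (
            "larger firms international companies tended offer "
            "biggest pay rises"
        ).split()
        assert max_separation_order(content) == (
            "larger international tended biggest rises "
            "firms companies offer pay"
        ).split()

    def test_printed_function_word_example(self):
        assert max_separation_order(["and", "to", "the"]) == [
            "and",
            "the",
            "to",
        ]

    def test_empty_and_singleton(self):
        assert max_separation_order([]) == []
        assert max_separation_order(["x"]) == ["x"]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7, 8, 9, 12])
    def test_adjacent_pairs_separated_by_half_length(self, n):
        # the interleave pushes every originally adjacent pair at least
        # floor((n-1)/2) positions apart
        original = list(range(n))
        out = max_separation_order(original)
        pos = {item: p for p, item in enumerate(out)}
        min_sep = min(
            abs(pos[a] - pos[b]) for a, b in zip(original, original[1:])
        )
        assert min_sep >= max(1, (n - 1) // 2)

    def test_preserves_relative_order_within_halves(self):
        original = list(range(9))
        out = max_separation_order(original)
        odd = [x for x in out if x % 2 == 0]
        even = [x for x in out if x % 2 == 1]
        assert odd == sorted(odd)
        assert even == sorted(even)

    def test_embedded_block_splits_every_adjacent_content_pair(self):
        # after center embedding, each originally adjacent content pair
        # straddles the function block, ending beyond the 4-word window
        sent = LabeledSentence.from_lexicon(
            "larger firms and international companies tended to offer "
            "the biggest pay rises".split(),
            {"and", "to", "the"},
        )
        rec = min_pmi_scramble(sent)
        out = list(rec.scrambled_tokens)
        content = [
            t for t, c in zip(sent.tokens, sent.word_class) if c == "content"
        ]
        pos = {w: i for i, w in enumerate(out)}
        for a, b in zip(content, content[1:]):
            assert abs(pos[a] - pos[b]) > 3


class TestMinPMIScramble:
    WORKED = "larger firms and international companies tended to offer the biggest pay rises"

    def worked_sentence(self) -> LabeledSentence:
        return LabeledSentence.from_lexicon(
            self.WORKED.split(), {"and", "to", "the"}
        )

    def test_reproduces_printed_output(self):
        rec = min_pmi_scramble(self.worked_sentence())
        assert " ".join(rec.scrambled_tokens) == (
            "larger international tended biggest rises and the to "
            "firms companies offer pay"
        )
        assert rec.condition_label == "ScrLowPMI"

    def test_worked_example_mean_separation(self):
        # originally adjacent content pairs end up alternating 8 and 7 apart
        rec = min_pmi_scramble(self.worked_sentence())
        out = list(rec.scrambled_tokens)
        content = [
            t
            for t, c in zip(
                self.worked_sentence().tokens,
                self.worked_sentence().word_class,
            )
            if c == "content"
        ]
        pos = {w: i for i, w in enumerate(out)}
        dists = [
            abs(pos[a] - pos[b]) for a, b in zip(content, content[1:])
        ]
        assert dists == [8, 7, 8, 7, 8, 7, 8, 7]
        assert np.mean(dists) == pytest.approx(7.5)

    def test_all_content_sentence_degenerates(self):
        sent = LabeledSentence.from_lexicon(list("abcde"), set())
        rec = min_pmi_scramble(sent)
        assert list(rec.scrambled_tokens) == max_separation_order(
            list("abcde")
        )

    def test_lowers_mean_positive_pmi_per_item(
        self, count_table, stimulus_set
    ):
        """Paired Int vs ScrLowPMI comparison: lower on >= 90% of items."""
        from scramblex.pmi_profile import string_profile

        rows = stimulus_set.rows
        intact = rows[rows["condition"] == "Int"].set_index("item_id")
        low = rows[rows["condition"] == "ScrLowPMI"].set_index("item_id")
        wins = 0
        items = stimulus_set.item_ids()
        for item in items:
            a = string_profile(
                count_table, intact.loc[item, "tokens"]
            ).mean_positive_pmi
            b = string_profile(
                count_table, low.loc[item, "tokens"]
            ).mean_positive_pmi
            wins += b < a
        assert wins >= 0.9 * len(items)


# ---------------------------------------------------------------------------
# characterization


class TestCharacterizeConditions:
    def test_summary_table(self, stimulus_set):
        table = sx.characterize_conditions(stimulus_set).set_index(
            "condition"
        )
        assert table.loc["Int", "mean_words_moved"] == 0
        assert table.loc["Int", "sd_words_moved"] == 0
        assert table.loc["Scr1", "mean_words_moved"] == 1
        assert table.loc["Scr1", "sd_words_moved"] == 0
        assert table.loc["Scr7", "mean_inversion_distance"] == 7

    def test_missing_intact_row_rejected(self):
        import pandas as pd

        rows = pd.DataFrame(
            [("i1", "Scr1", ("b", "a"), (1, 0))],
            columns=["item_id", "condition", "tokens", "permutation"],
        )
        with pytest.raises(ValueError, match="missing Int row"):
            sx.characterize_conditions(sx.StimulusSet(rows=rows))
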