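"""Sentence-scrambling algorithms and word-order degradation metrics.

Two scramblers are provided:

* **Local swaps** — ``k`` repeated exchanges of a randomly chosen word with
  one of its immediate neighbors.  Because one random swap can undo a
  previous one, the draw is rejected and resampled until the realized
  inversion (Kendall-tau) distance from the original order equals ``k``,
  so the requested and achieved degradation always agree.
* **PMI-minimizing separation** — content words are reordered so that the
  sum of the distances between originally adjacent content words is
  maximized (an odd-then-even interleave attains the maximum), the
  function words are reordered the same way, and the function block is
  embedded in the center of the content words.  Words that co-occurred
  locally in the original sentence end up far apart, minimizing local
  mutual information.

Degradation is measured by the inversion distance (minimum number of
adjacent transpositions between two orders) and by *words moved*: the
minimal number of words displaced, formalized as sequence length minus the
length of the longest common subsequence of the two surface strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "ScrambleRecord",
    "LabeledSentence",
    "StimulusSet",
    "local_swap_scramble",
    "inversion_distance",
    "words_moved",
    "max_separation_order",
    "min_pmi_scramble",
    "characterize_conditions",
    "apply_permutation",
]

DEFAULT_MAX_RETRIES = 10_000


class Condition(str, Enum):
    """Stimulus conditions: intact, k-swap scrambles, low-PMI, word list."""

    INT = "Int"
    SCR1 = "Scr1"
    SCR3 = "Scr3"
    SCR5 = "Scr5"
    SCR7 = "Scr7"
    SCR_LOW_PMI = "ScrLowPMI"
    WORD_LIST = "WordList"


def scr_condition(k: int) -> str:
    return f"Scr{k}"


@dataclass
class ScrambleRecord:
    """An intact token sequence plus a permutation of its indices.

    ``permutation[p]`` is the 0-based original index of the token now at
    output position ``p``.  ``realized_inversion_distance`` is always the
    inversion distance between the identity and the stored permutation; for
    local-swap records it equals ``requested_swaps`` by construction.
    """

    original_tokens: tuple
    permutation: tuple
    requested_swaps: int = 0
    realized_inversion_distance: int = 0
    seed: int | None = None
    condition_label: str = Condition.INT.value

    @property
    def scrambled_tokens(self) -> tuple:
        return tuple(self.original_tokens[i] for i in self.permutation)

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.original_tokens))):
            raise ValueError("permutation is not a bijection on 0..n-1")


@dataclass
class LabeledSentence:
    """Tokens with a content/function class label per position."""

    tokens: tuple
    word_class: tuple  # "content" | "function" per token

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.word_class):
            raise ValueError("tokens and word_class lengths differ")
        if len(self.tokens) < 1:
            raise ValueError("sentence must have at least 1 token")
        bad = set(self.word_class) - {"content", "function"}
        if bad:
            raise ValueError(f"unknown word classes: {sorted(bad)}")

    @classmethod
    def from_lexicon(
        cls, tokens: Sequence[str], function_words: set[str]
    ) -> "LabeledSentence":
        classes = tuple(
            "function" if t.lower() in function_words else "content"
            for t in tokens
        )
        return cls(tokens=tuple(tokens), word_class=classes)


@dataclass
class StimulusSet:
    """Items x conditions, each row a token sequence with its permutation.

    ``rows`` is a DataFrame with columns item_id, condition, tokens
    (tuple), permutation (tuple of 0-based indices into the item's Int
    row; the identity for WordList rows, whose tokens are replacements
    rather than reorderings).
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["item_id", "condition", "tokens", "permutation"]
        )
    )

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.rows["condition"]))

    def item_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["item_id"]))


# ---------------------------------------------------------------------------
# order metrics


def _inversions(perm: Sequence[int]) -> int:
    """Inversion count via merge sort, O(n log n)."""

    def sort_count(a: list[int]) -> tuple[list[int], int]:
        if len(a) <= 1:
            return a, 0
        mid = len(a) // 2
        left, nl = sort_count(a[:mid])
        right, nr = sort_count(a[mid:])
        merged: list[int] = []
        inv = nl + nr
        i = j = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                inv += len(left) - i
                merged.append(right[j])
                j += 1
        merged.extend(left[i:])
        merged.extend(right[j:])
        return merged, inv

    return sort_count(list(perm))[1]


def inversion_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Minimum number of adjacent transpositions converting order a to b.

    Equals the Kendall-tau inversion count of the relative permutation.
    Both arguments are orderings of the same index set.
    """
    if sorted(a) != sorted(b) or len(set(a)) != len(a):
        raise ValueError("a and b must be orders of the same index set")
    pos_in_b = {v: p for p, v in enumerate(b)}
    relative = [pos_in_b[v] for v in a]
    return _inversions(relative)


def words_moved(
    original: Sequence[str], scrambled: Sequence[str]
) -> int:
    """Minimal number of words displaced between two orderings.

    Defined as n minus the length of the longest common subsequence of the
    two surface strings; LCS matching resolves duplicate words optimally,
    so each moved word is counted once regardless of how far it traveled.
    """
    if sorted(original) != sorted(scrambled):
        raise ValueError("scrambled is not a permutation of original tokens")
    n, m = len(original), len(scrambled)
    # standard LCS DP on surface forms
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        oi = original[i - 1]
        for j in range(1, m + 1):
            if oi == scrambled[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return n - prev[m]


# ---------------------------------------------------------------------------
# local-swap scrambling


def local_swap_scramble(
    tokens: Sequence[str],
    k: int,
    seed: int,
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> ScrambleRecord:
    """Scramble by k local word swaps with the realized distance enforced.

    Each swap picks a word uniformly at random and exchanges it with an
    immediate neighbor (endpoints use their only neighbor; interior words
    pick a side uniformly).  The whole k-swap draw is rejected and
    resampled until the inversion distance of the resulting permutation —
    computed on token indices, so duplicate words are distinguished —
    equals k.  Deterministic given the seed.
    """
    n = len(tokens)
    if n < 2:
        raise ValueError("need at least 2 tokens to swap")
    max_dist = n * (n - 1) // 2
    if not 0 <= k <= max_dist:
        raise ValueError(f"k={k} outside [0, {max_dist}] for n={n}")
    rng = np.random.default_rng(seed)
    identity = list(range(n))
    for _ in range(max_retries):
        perm = identity.copy()
        for _ in range(k):
            pos = int(rng.integers(n))
            if pos == 0:
                nb = 1
            elif pos == n - 1:
                nb = n - 2
            else:
                nb = pos + 1 if rng.integers(2) else pos - 1
            perm[pos], perm[nb] = perm[nb], perm[pos]
        realized = _inversions(perm)
        if realized == k:
            return ScrambleRecord(
                original_tokens=tuple(tokens),
                permutation=tuple(perm),
                requested_swaps=k,
                realized_inversion_distance=realized,
                seed=seed,
                condition_label=scr_condition(k) if k else Condition.INT.value,
            )
    raise RuntimeError(
        f"no k={k} draw reached inversion distance {k} after "
        f"{max_retries} retries (seed={seed})"
    )


# ---------------------------------------------------------------------------
# PMI-minimizing scrambling


def max_separation_order(items: Sequence) -> list:
    """Reorder so originally adjacent items end up maximally separated.

    Returns the odd-position items (1st, 3rd, 5th, ...) in original
    relative order followed by the even-position items (2nd, 4th, ...).
    At unit spacing this interleave attains the maximum, over all
    permutations, of the summed position distances between originally
    adjacent pairs.
    """
    items = list(items)
    return items[0::2] + items[1::2]


def min_pmi_scramble(sentence: LabeledSentence) -> ScrambleRecord:
    """Separate nearby content words as much as possible within the string.

    Content words (adjacency defined on the original string: two content
    words are adjacent if no content word lies between them) are reordered
    by :func:`max_separation_order`; the function words are reordered the
    same way and the function block is inserted after the first
    ceil(c/2) content words, i.e. in the center of the content ordering.
    All-content and all-function sentences degenerate to a single
    max-separation reorder.
    """
    content_idx = [
        i for i, c in enumerate(sentence.word_class) if c == "content"
    ]
    function_idx = [
        i for i, c in enumerate(sentence.word_class) if c == "function"
    ]
    content_order = max_separation_order(content_idx)
    function_order = max_separation_order(function_idx)
    half = math.ceil(len(content_order) / 2)
    perm = content_order[:half] + function_order + content_order[half:]
    return ScrambleRecord(
        original_tokens=sentence.tokens,
        permutation=tuple(perm),
        requested_swaps=0,
        realized_inversion_distance=inversion_distance(
            list(range(len(perm))), list(perm)
        ),
        seed=None,
        condition_label=Condition.SCR_LOW_PMI.value,
    )


def apply_permutation(tokens: Sequence[str], perm: Sequence[int]) -> tuple:
    return tuple(tokens[i] for i in perm)


# ---------------------------------------------------------------------------
# characterization


def characterize_conditions(stimulus_set: StimulusSet) -> pd.DataFrame:
    """Mean and SD of words moved and inversion distance per condition.

    Every condition row must be a permutation of its item's Int row;
    WordList rows (token replacements, not reorderings) are exempt and
    reported with NaN metrics.
    """
    rows = stimulus_set.rows
    intact = {
        r.item_id: tuple(r.tokens)
        for r in rows[rows["condition"] == Condition.INT.value].itertuples()
    }
    records = []
    for r in rows.itertuples():
        if r.condition == Condition.WORD_LIST.value:
            records.append((r.condition, np.nan, np.nan))
            continue
        if r.item_id not in intact:
            raise ValueError(f"missing Int row for item {r.item_id!r}")
        orig = intact[r.item_id]
        toks = tuple(r.tokens)
        moved = words_moved(orig, toks)
        dist = inversion_distance(
            list(range(len(orig))), list(r.permutation)
        )
        records.append((r.condition, moved, dist))
    df = pd.DataFrame(
        records, columns=["condition", "words_moved", "inversion_distance"]
    )
    out = df.groupby("condition", sort=False).agg(
        n_items=("words_moved", "size"),
        mean_words_moved=("words_moved", "mean"),
        sd_words_moved=("words_moved", lambda s: s.std(ddof=1)),
        mean_inversion_distance=("inversion_distance", "mean"),
        sd_inversion_distance=(
            "inversion_distance",
            lambda s: s.std(ddof=1),
        ),
    )
    return out.reset_index()
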