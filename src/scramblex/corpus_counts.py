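"""Smoothed unigram and windowed ordered-pair co-occurrence statistics.

Word pairs are extracted with a forward sliding window of ``window`` tokens:
every ordered pair (token at position i, token at position j) with
1 <= j - i <= window - 1 is counted, and the gap j - i is recorded.  With the
default four-word window this collects the bigrams, 1-skip-grams and
2-skip-grams of each string.  Probabilities are Laplace-smoothed with
pseudo-count ``alpha`` (default 0.1), using the vocabulary size V as the
smoothed support for unigrams and V**2 for ordered pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["CountTable", "count_corpus", "unigram_prob", "pair_prob"]

DEFAULT_WINDOW = 4
DEFAULT_ALPHA = 0.1


@dataclass
class CountTable:
    """Unigram and ordered-pair counts plus smoothing parameters.

    Pair counts are keyed by ``(w_i, w_j, gap)`` where ``w_i`` precedes
    ``w_j`` by ``gap`` positions (gap in 1..window-1).  ``vocab_size`` may
    exceed the number of observed types when an external vocabulary is
    assumed.
    """

    unigram_counts: Counter = field(default_factory=Counter)
    pair_counts: Counter = field(default_factory=Counter)
    total_tokens: int = 0
    total_pairs: int = 0
    vocab_size: int = 0
    alpha: float = DEFAULT_ALPHA
    window: int = DEFAULT_WINDOW
    lowercase: bool = True

    _gap_totals: dict | None = field(default=None, repr=False, compare=False)

    def pair_total_at_gap(self, gap: int) -> int:
        if self._gap_totals is None:
            totals: dict[int, int] = {}
            for (_, _, g), c in self.pair_counts.items():
                totals[g] = totals.get(g, 0) + c
            self._gap_totals = totals
        return self._gap_totals.get(gap, 0)

    def pooled_pair_count(self, wi: str, wj: str) -> int:
        return sum(
            self.pair_counts.get((wi, wj, g), 0) for g in range(1, self.window)
        )

    def validate(self) -> None:
        if self.total_tokens != sum(self.unigram_counts.values()):
            raise ValueError("total_tokens does not match unigram counts")
        if self.total_pairs != sum(self.pair_counts.values()):
            raise ValueError("total_pairs does not match pair counts")
        if any(c < 0 for c in self.unigram_counts.values()):
            raise ValueError("negative unigram count")
        if any(c < 0 for c in self.pair_counts.values()):
            raise ValueError("negative pair count")
        n_types = sum(1 for c in self.unigram_counts.values() if c > 0)
        if self.vocab_size < n_types:
            raise ValueError(
                f"vocab_size {self.vocab_size} < {n_types} observed types"
            )


def _normalize(token: str, lowercase: bool) -> str:
    return token.lower() if lowercase else token


def count_corpus(
    corpus: Iterable[Sequence[str]],
    window: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    lowercase: bool = True,
    vocab_size: int | None = None,
) -> CountTable:
    """Tally unigrams and windowed ordered pairs over a tokenized corpus.

    Parameters
    ----------
    corpus
        Iterable of token sequences (one per sentence).  Sentences shorter
        than 2 tokens contribute only unigrams; pairs never cross sentence
        boundaries.
    window
        Sliding-window width; pairs at gaps 1..window-1 are extracted.
    vocab_size
        Override for V; defaults to the number of distinct tokens seen.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    table = CountTable(alpha=alpha, window=window, lowercase=lowercase)
    n_sentences = 0
    for sentence in corpus:
        n_sentences += 1
        toks = [_normalize(t, lowercase) for t in sentence]
        if any(not t for t in toks):
            raise ValueError("tokens must be non-empty strings")
        table.unigram_counts.update(toks)
        n = len(toks)
        for i in range(n):
            for gap in range(1, window):
                j = i + gap
                if j >= n:
                    break
                table.pair_counts[(toks[i], toks[j], gap)] += 1
    if n_sentences == 0:
        raise ValueError("empty corpus")
    table.total_tokens = sum(table.unigram_counts.values())
    table.total_pairs = sum(table.pair_counts.values())
    table.vocab_size = (
        vocab_size if vocab_size is not None else len(table.unigram_counts)
    )
    table.validate()
    return table


def unigram_prob(table: CountTable, w: str) -> float:
    """Smoothed unigram probability (count(w) + a) / (N + a*V).

    Out-of-vocabulary words use count 0; with alpha > 0 the result is
    always strictly positive.
    """
    if table.total_tokens == 0:
        raise ValueError("empty count table (total_tokens == 0)")
    w = _normalize(w, table.lowercase)
    count = table.unigram_counts.get(w, 0)
    return (count + table.alpha) / (
        table.total_tokens + table.alpha * table.vocab_size
    )


def pair_prob(
    table: CountTable,
    wi: str,
    wj: str,
    pooled_gaps: bool = True,
    gap: int | None = None,
) -> float:
    """Smoothed joint probability of the ordered pair (wi, wj).

    With ``pooled_gaps`` (the default) counts are summed over gaps
    1..window-1 and normalized by the grand pair total; otherwise the
    per-``gap`` count and that gap's total are used.  The smoothed support
    is the V**2 ordered pairs in both cases.
    """
    if table.total_pairs == 0:
        raise ValueError("empty count table (total_pairs == 0)")
    wi = _normalize(wi, table.lowercase)
    wj = _normalize(wj, table.lowercase)
    v2 = table.vocab_size**2
    if pooled_gaps:
        count = table.pooled_pair_count(wi, wj)
        total = table.total_pairs
    else:
        if gap is None:
            raise ValueError("gap is required when pooled_gaps is False")
        count = table.pair_counts.get((wi, wj, gap), 0)
        total = table.pair_total_at_gap(gap)
        if total == 0:
            raise ValueError(f"no pairs observed at gap {gap}")
    return (count + table.alpha) / (total + table.alpha * v2)
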