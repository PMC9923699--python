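"""Pointwise mutual information profiles of token strings.

PMI(wi, wj) = ln P(wi, wj) / (P(wi) P(wj)), in nats, with the probabilities
taken from a smoothed :class:`~scramblex.corpus_counts.CountTable`.  The
per-string statistic is the mean over the *positive* PMI values of all word
pairs extracted with the same sliding window used to build the counts; a
string whose pairs are all non-positive scores 0 by convention.  Strings are
treated as isolated: no padding, no cross-string pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_counts import DEFAULT_WINDOW, CountTable, pair_prob, unigram_prob

__all__ = ["PMIProfile", "pmi", "string_profile", "pmi_by_distance"]


@dataclass
class PMIProfile:
    """Per-string PMI summary: every windowed pair plus the positive mean."""

    string_id: str
    pair_pmis: list = field(default_factory=list)  # (wi, wj, gap, pmi)
    mean_positive_pmi: float = 0.0
    n_positive_pairs: int = 0
    n_pairs: int = 0


def pmi(
    table: CountTable,
    wi: str,
    wj: str,
    pooled_gaps: bool = True,
    gap: int | None = None,
) -> float:
    """Natural-log PMI of the ordered pair (wi, wj); finite when alpha > 0."""
    p_joint = pair_prob(table, wi, wj, pooled_gaps=pooled_gaps, gap=gap)
    p_i = unigram_prob(table, wi)
    p_j = unigram_prob(table, wj)
    if p_joint == 0.0 or p_i == 0.0 or p_j == 0.0:
        raise ValueError(
            "zero probability (alpha = 0 with unseen word); PMI undefined"
        )
    return math.log(p_joint / (p_i * p_j))


def string_profile(
    table: CountTable,
    tokens: Sequence[str],
    window: int = DEFAULT_WINDOW,
    string_id: str = "",
    pooled_gaps: bool = True,
) -> PMIProfile:
    """Mean positive PMI over all windowed word pairs of one string.

    Pair extraction matches corpus counting exactly (ordered pairs at gaps
    1..window-1).  Every pair occurrence counts — repeated pair types are
    not deduplicated.  Strings with fewer than 2 tokens yield an empty
    profile with mean 0.
    """
    profile = PMIProfile(string_id=string_id)
    n = len(tokens)
    for i in range(n):
        for g in range(1, window):
            j = i + g
            if j >= n:
                break
            value = pmi(table, tokens[i], tokens[j], pooled_gaps=pooled_gaps)
            profile.pair_pmis.append((tokens[i], tokens[j], g, value))
    profile.n_pairs = len(profile.pair_pmis)
    positives = [v for (_, _, _, v) in profile.pair_pmis if v > 0]
    profile.n_positive_pairs = len(positives)
    profile.mean_positive_pmi = (
        sum(positives) / len(positives) if positives else 0.0
    )
    return profile


def pmi_by_distance(
    table: CountTable,
    corpus: Iterable[Sequence[str]],
    max_gap: int,
) -> list[tuple[int, float]]:
    """Mean PMI at each interword distance 1..max_gap over a corpus.

    Uses gap-specific joint probabilities, so the decay of association with
    distance is visible rather than pooled away.  Gaps longer than every
    sentence are omitted from the output.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    sums: dict[int, float] = {g: 0.0 for g in range(1, max_gap + 1)}
    counts: dict[int, int] = {g: 0 for g in range(1, max_gap + 1)}
    for sentence in corpus:
        n = len(sentence)
        for i in range(n):
            for g in range(1, max_gap + 1):
                j = i + g
                if j >= n:
                    break
                sums[g] += pmi(
                    table, sentence[i], sentence[j], pooled_gaps=False, gap=g
                )
                counts[g] += 1
    return [
        (g, sums[g] / counts[g])
        for g in range(1, max_gap + 1)
        if counts[g] > 0
    ]
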