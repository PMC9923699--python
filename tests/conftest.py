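"""Shared fixtures: hand-built count tables and a default synthetic corpus."""

from collections import Counter

import pytest

import scramblex as sx


@pytest.fixture
def tiny_table() -> sx.CountTable:
    """Unigrams {a:3, b:1}, one pooled pair (a,b):2, V=2, alpha=0.1."""
    return sx.CountTable(
        unigram_counts=Counter({"a": 3, "b": 1}),
        pair_counts=Counter({("a", "b", 1): 2}),
        total_tokens=4,
        total_pairs=2,
        vocab_size=2,
        alpha=0.1,
    )


@pytest.fixture(scope="session")
def grammar() -> sx.ToyGrammar:
    return sx.default_grammar()


@pytest.fixture(scope="session")
def corpus(grammar):
    """~10^5 tokens of the default template language."""
    return sx.sample_corpus(grammar, 8500, seed=11)


@pytest.fixture(scope="session")
def count_table(corpus) -> sx.CountTable:
    return sx.count_corpus(corpus)


@pytest.fixture(scope="session")
def stimulus_set(grammar) -> sx.StimulusSet:
    """150 items x 7 conditions from the default grammar."""
    return sx.make_stimulus_set(grammar, 150, seed=22)
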