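"""File formats, configuration, and the end-to-end pipeline driver.

All tabular outputs are UTF-8 TSV with a header line.  Token positions in
serialized permutations are 1-based, matching how stimulus orderings are
written out for human inspection.  The pipeline runs
simulation -> scrambling -> PMI profiling -> characterization -> effect
estimation and records a provenance manifest (inputs, seeds, versions,
per-stage row counts); reruns with the same configuration are
byte-identical except for the manifest timestamp.
"""

from __future__ import annotations

import datetime
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import ContrastScheme, estimate_effects
from .corpus_counts import CountTable, count_corpus
from .pmi_profile import string_profile
from .scramble import StimulusSet, characterize_conditions
from .synthetic_data import (
    default_grammar,
    make_stimulus_set,
    neural_params,
    sample_corpus,
    simulate_responses,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_sentences",
    "read_lexicon",
    "read_counts",
    "write_counts",
    "read_stimuli",
    "write_stimuli",
    "read_responses",
    "write_responses",
    "write_profiles",
    "write_estimates",
]

logger = logging.getLogger("scramblex")


# ---------------------------------------------------------------------------
# readers / writers


def read_sentences(path: str | Path) -> list[list[str]]:
    """One sentence per line, space-separated tokens; blank lines rejected."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                raise ValueError(f"{path}:{lineno}: sentence with zero tokens")
            sentences.append(tokens)
    if not sentences:
        raise ValueError(f"{path}: empty sentence file")
    return sentences


def read_lexicon(path: str | Path) -> set[str]:
    """One word per line; duplicates deduplicated with a logged warning."""
    words: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip().lower()
            if word:
                words.append(word)
    dupes = [w for w, c in Counter(words).items() if c > 1]
    if dupes:
        logger.warning("lexicon %s: duplicate words deduplicated: %s", path, dupes)
    return set(words)


def write_counts(table: CountTable, out_dir: str | Path) -> list[Path]:
    """Serialize a CountTable to unigrams.tsv / pairs.tsv / meta.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    uni = out_dir / "unigrams.tsv"
    with open(uni, "w", encoding="utf-8") as fh:
        fh.write("word\tcount\n")
        for w in sorted(table.unigram_counts):
            fh.write(f"{w}\t{table.unigram_counts[w]}\n")
    pairs = out_dir / "pairs.tsv"
    with open(pairs, "w", encoding="utf-8") as fh:
        fh.write("w1\tw2\tgap\tcount\n")
        for (w1, w2, gap) in sorted(table.pair_counts):
            fh.write(f"{w1}\t{w2}\t{gap}\t{table.pair_counts[(w1, w2, gap)]}\n")
    meta = out_dir / "meta.tsv"
    with open(meta, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"vocab_size\t{table.vocab_size}\n")
        fh.write(f"alpha\t{table.alpha!r}\n")
        fh.write(f"window\t{table.window}\n")
        fh.write(f"lowercase\t{int(table.lowercase)}\n")
    return [uni, pairs, meta]


def _read_tsv_rows(path: Path, expected_header: str) -> list[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != expected_header:
        raise ValueError(f"{path}:1: expected header {expected_header!r}")
    n_cols = len(expected_header.split("\t"))
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
            )
        rows.append((lineno, fields))
    return rows


def read_counts(count_dir: str | Path) -> CountTable:
    """Load a CountTable serialized by :func:`write_counts`."""
    count_dir = Path(count_dir)
    table = CountTable()
    for lineno, (w, c) in _read_tsv_rows(
        count_dir / "unigrams.tsv", "word\tcount"
    ):
        try:
            table.unigram_counts[w] = int(c)
        except ValueError as err:
            raise ValueError(
                f"{count_dir / 'unigrams.tsv'}:{lineno}: bad count {c!r}"
            ) from err
    for lineno, (w1, w2, gap, c) in _read_tsv_rows(
        count_dir / "pairs.tsv", "w1\tw2\tgap\tcount"
    ):
        try:
            table.pair_counts[(w1, w2, int(gap))] = int(c)
        except ValueError as err:
            raise ValueError(
                f"{count_dir / 'pairs.tsv'}:{lineno}: bad gap/count"
            ) from err
    meta = dict(
        fields for _, fields in _read_tsv_rows(count_dir / "meta.tsv", "key\tvalue")
    )
    table.vocab_size = int(meta["vocab_size"])
    table.alpha = float(meta["alpha"])
    table.window = int(meta["window"])
    table.lowercase = bool(int(meta["lowercase"]))
    table.total_tokens = sum(table.unigram_counts.values())
    table.total_pairs = sum(table.pair_counts.values())
    table.validate()
    return table


def write_stimuli(stimuli: StimulusSet, path: str | Path) -> Path:
    """Stimulus TSV: item_id, condition, tokens, 1-based permutation."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("item_id\tcondition\ttokens\tpermutation\n")
        for r in stimuli.rows.itertuples():
            toks = " ".join(r.tokens)
            perm = ",".join(str(i + 1) for i in r.permutation)
            fh.write(f"{r.item_id}\t{r.condition}\t{toks}\t{perm}\n")
    return path


def read_stimuli(path: str | Path) -> StimulusSet:
    """Load a stimulus TSV, validating every permutation."""
    records = []
    for lineno, (item_id, condition, toks, perm) in _read_tsv_rows(
        Path(path), "item_id\tcondition\ttokens\tpermutation"
    ):
        tokens = tuple(toks.split())
        try:
            indices = tuple(int(i) - 1 for i in perm.split(","))
        except ValueError as err:
            raise ValueError(
                f"{path}:{lineno}: item {item_id!r}: bad permutation {perm!r}"
            ) from err
        if sorted(indices) != list(range(len(tokens))):
            raise ValueError(
                f"{path}:{lineno}: item {item_id!r}: permutation is not a "
                f"bijection on 1..{len(tokens)}"
            )
        records.append((item_id, condition, tokens, indices))
    rows = pd.DataFrame(
        records, columns=["item_id", "condition", "tokens", "permutation"]
    )
    return StimulusSet(rows=rows)


def write_responses(data: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("participant\tunit\tcondition\tvalue\n")
        for r in data.itertuples():
            fh.write(f"{r.participant}\t{r.unit}\t{r.condition}\t{r.value!r}\n")
    return path


def read_responses(path: str | Path) -> pd.DataFrame:
    records = []
    for lineno, (p, u, c, v) in _read_tsv_rows(
        Path(path), "participant\tunit\tcondition\tvalue"
    ):
        try:
            records.append((p, u, c, float(v)))
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: bad value {v!r}") from err
    return pd.DataFrame(
        records, columns=["participant", "unit", "condition", "value"]
    )


def write_profiles(profiles, path: str | Path) -> Path:
    """Profile TSV: string_id, condition, n_pairs, n_positive, mean PMI."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("string_id\tcondition\tn_pairs\tn_positive\tmean_positive_pmi\n")
        for condition, prof in profiles:
            fh.write(
                f"{prof.string_id}\t{condition}\t{prof.n_pairs}\t"
                f"{prof.n_positive_pairs}\t{prof.mean_positive_pmi:.6f}\n"
            )
    return path


def write_estimates(estimates, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("contrast\testimate\tci_low\tci_high\tn_clusters\n")
        for e in estimates:
            fh.write(
                f"{e.name}\t{e.estimate:.6f}\t{e.ci_low:.6f}\t"
                f"{e.ci_high:.6f}\t{e.n_clusters}\n"
            )
    return path


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """End-to-end demo pipeline settings; all stages seeded independently."""

    output_dir: str = "scramblex_out"
    n_corpus_sentences: int = 2000
    n_items: int = 50
    swap_levels: tuple = (1, 3, 5, 7)
    window: int = 4
    alpha: float = 0.1
    n_boot: int = 1000
    scheme: str = "dummy"
    reference: str = "Int"
    seeds: dict = field(
        default_factory=lambda: {
            "corpus": 101,
            "stimuli": 202,
            "responses": 303,
            "bootstrap": 404,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "swap_levels" in raw:
            raw["swap_levels"] = tuple(raw["swap_levels"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulation -> scrambling -> PMI -> characterization -> effects.

    Returns the provenance manifest (also written to manifest.json in the
    output directory).  Any stage failure aborts with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grammar = default_grammar()
    stages: dict[str, dict] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    name = stage("corpus_counts")
    try:
        corpus = sample_corpus(
            grammar, config.n_corpus_sentences, seed=config.seeds["corpus"]
        )
        table = count_corpus(corpus, window=config.window, alpha=config.alpha)
        count_files = write_counts(table, out / "counts")
        stages[name] = {
            "outputs": [str(p) for p in count_files],
            "rows": table.total_tokens,
        }

        name = stage("stimuli")
        stimuli = make_stimulus_set(
            grammar,
            config.n_items,
            swap_levels=config.swap_levels,
            seed=config.seeds["stimuli"],
        )
        stim_path = write_stimuli(stimuli, out / "stimuli.tsv")
        stages[name] = {"outputs": [str(stim_path)], "rows": len(stimuli.rows)}

        name = stage("pmi_profiles")
        profiles = [
            (
                r.condition,
                string_profile(
                    table,
                    r.tokens,
                    window=config.window,
                    string_id=r.item_id,
                ),
            )
            for r in stimuli.rows.itertuples()
        ]
        prof_path = write_profiles(profiles, out / "pmi_profiles.tsv")
        stages[name] = {"outputs": [str(prof_path)], "rows": len(profiles)}

        name = stage("characterization")
        character = characterize_conditions(stimuli)
        char_path = out / "characterization.tsv"
        character.to_csv(char_path, sep="\t", index=False)
        stages[name] = {"outputs": [str(char_path)], "rows": len(character)}

        name = stage("effects")
        params = neural_params(seed=config.seeds["responses"])
        responses = simulate_responses(
            [c for c in stimuli.conditions() if c in params.condition_means],
            params,
        )
        resp_path = write_responses(responses, out / "responses.tsv")
        scheme = ContrastScheme(
            scheme=config.scheme,
            levels=tuple(sorted(set(responses["condition"]), key=list(
                params.condition_means
            ).index)),
            reference=config.reference if config.scheme == "dummy" else None,
        )
        estimates = estimate_effects(
            responses,
            scheme,
            n_boot=config.n_boot,
            seed=config.seeds["bootstrap"],
        )
        est_path = write_estimates(estimates, out / "estimates.tsv")
        stages[name] = {
            "outputs": [str(resp_path), str(est_path)],
            "rows": len(estimates),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in config.__dict__.items()
            }
        },
        "stages": stages,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
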