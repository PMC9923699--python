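"""Condition-effect estimation with dummy or backwards-difference contrasts.

The estimator is a two-stage cluster bootstrap: stage 1 collapses the
long-format response table to per-participant condition means (or, for
accuracy data, per-participant log-odds with a 0.5 continuity correction);
stage 2 applies the contrast weights to those means and reports the
across-participant average with percentile bootstrap confidence intervals
obtained by resampling participants.  This targets the same estimands as a
mixed model with participant random effects — condition contrasts — while
remaining dependency-free and exactly reproducible under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContrastScheme",
    "EffectEstimate",
    "contrast_matrix",
    "estimate_effects",
    "accuracy_summary",
]

logger = logging.getLogger("scramblex")

DEFAULT_N_BOOT = 5000


@dataclass
class ContrastScheme:
    """Which contrasts to estimate over an ordered set of condition levels.

    ``dummy`` compares every level against a reference; ``backwards_difference``
    compares each level against the preceding one.
    """

    scheme: str
    levels: tuple
    reference: str | None = None

    def __post_init__(self) -> None:
        self.levels = tuple(self.levels)
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("levels must be distinct")
        if self.scheme not in ("dummy", "backwards_difference"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "dummy":
            if self.reference is None:
                self.reference = self.levels[0]
            if self.reference not in self.levels:
                raise ValueError(
                    f"reference {self.reference!r} not among levels"
                )


@dataclass
class EffectEstimate:
    """A contrast point estimate with a percentile 95% CI."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n_clusters: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("estimate outside its CI bounds")

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def contrast_matrix(scheme: ContrastScheme) -> pd.DataFrame:
    """Coding matrix (levels x contrasts) for the requested scheme.

    Dummy coding yields indicator columns for each non-reference level.
    Backwards-difference coding yields the standard columns whose fitted
    coefficients, in balanced noise-free data, equal the successive
    differences mean(level j+1) - mean(level j).
    """
    levels = scheme.levels
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 levels")
    if scheme.scheme == "dummy":
        cols = {}
        for lev in levels:
            if lev == scheme.reference:
                continue
            cols[f"{lev} versus {scheme.reference}"] = [
                1.0 if l == lev else 0.0 for l in levels
            ]
        return pd.DataFrame(cols, index=levels)
    # backwards difference: level rows 1..j get -(k-j)/k, rows j+1..k get j/k
    cols = {}
    for j in range(1, k):
        name = f"{levels[j]} - {levels[j - 1]}"
        cols[name] = [
            -(k - j) / k if i < j else j / k for i in range(k)
        ]
    return pd.DataFrame(cols, index=levels)


def contrast_weights(scheme: ContrastScheme) -> pd.DataFrame:
    """Hypothesis weights (contrasts x levels) applied to condition means.

    Derived as the non-intercept rows of the inverse of [1 | coding
    matrix], so each contrast is the linear combination of level means its
    coding column estimates (e.g. +1/-1 successive differences for the
    backwards-difference scheme).
    """
    coding = contrast_matrix(scheme)
    x = np.column_stack([np.ones(len(scheme.levels)), coding.to_numpy()])
    weights = np.linalg.inv(x)[1:, :]
    return pd.DataFrame(
        weights, index=list(coding.columns), columns=list(scheme.levels)
    )


def _participant_level_matrix(
    data: pd.DataFrame,
    scheme: ContrastScheme,
    aggregator,
) -> tuple[np.ndarray, list[str]]:
    """Participants x levels matrix of stage-1 summaries, cells validated."""
    required = {"participant", "condition", "value"}
    missing_cols = required - set(data.columns)
    if missing_cols:
        raise ValueError(f"response table lacks columns: {sorted(missing_cols)}")
    participants = sorted(data["participant"].unique())
    cells = data.groupby(["participant", "condition"])["value"]
    summaries = aggregator(cells)
    missing = [
        (p, lev)
        for p in participants
        for lev in scheme.levels
        if (p, lev) not in summaries.index
    ]
    if missing:
        raise ValueError(f"missing (participant, condition) cells: {missing}")
    matrix = np.array(
        [[summaries.loc[(p, lev)] for lev in scheme.levels] for p in participants]
    )
    return matrix, participants


def _bootstrap_contrasts(
    per_participant: np.ndarray,
    names: Sequence[str],
    n_boot: int,
    seed: int,
) -> list[EffectEstimate]:
    if n_boot < 100:
        logger.warning(
            "n_boot=%d is below 100; confidence intervals will be unstable",
            n_boot,
        )
    n = per_participant.shape[0]
    rng = np.random.default_rng(seed)
    estimates = per_participant.mean(axis=0)
    idx = rng.integers(n, size=(n_boot, n))
    boot_means = per_participant[idx].mean(axis=1)  # n_boot x contrasts
    lo = np.percentile(boot_means, 2.5, axis=0)
    hi = np.percentile(boot_means, 97.5, axis=0)
    return [
        EffectEstimate(
            name=name,
            estimate=float(est),
            ci_low=float(min(l, est)),
            ci_high=float(max(h, est)),
            n_clusters=n,
        )
        for name, est, l, h in zip(names, estimates, lo, hi)
    ]


def estimate_effects(
    data: pd.DataFrame,
    scheme: ContrastScheme,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> list[EffectEstimate]:
    """Contrast estimates with participant-cluster bootstrap 95% CIs.

    Stage 1 averages each participant's observations within condition
    (over items / units); stage 2 applies the contrast weights to the
    per-participant means and bootstraps the across-participant mean by
    resampling participants.  Deterministic given ``seed``.
    """
    matrix, _ = _participant_level_matrix(
        data, scheme, aggregator=lambda cells: cells.mean()
    )
    weights = contrast_weights(scheme)
    per_participant = matrix @ weights.to_numpy().T
    return _bootstrap_contrasts(
        per_participant, list(weights.index), n_boot, seed
    )


def accuracy_summary(
    data: pd.DataFrame,
    scheme: ContrastScheme,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> list[EffectEstimate]:
    """As :func:`estimate_effects` but on per-participant log-odds.

    Stage 1 computes log((successes + 0.5) / (failures + 0.5)) per
    participant-condition cell, so all-correct or all-wrong cells remain
    finite; contrasts are therefore on the log-odds scale.
    """
    values = set(np.unique(data["value"]))
    if not values <= {0, 0.0, 1, 1.0}:
        raise ValueError("accuracy outcomes must be 0/1")

    def log_odds(cells):
        s = cells.sum()
        n = cells.count()
        return np.log((s + 0.5) / (n - s + 0.5))

    matrix, _ = _participant_level_matrix(data, scheme, aggregator=log_odds)
    weights = contrast_weights(scheme)
    per_participant = matrix @ weights.to_numpy().T
    return _bootstrap_contrasts(
        per_participant, list(weights.index), n_boot, seed
    )
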