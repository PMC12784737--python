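"""Banding-pattern statistics and minimal-panel selection.

A sample's banding pattern at a locus is its full presence/absence
vector over the locus's alleles; two samples sharing a pattern are
indistinguishable there.  With pattern frequencies p_i (i = 1..I over N
scored samples) the confusion probability

    C_j = sum_i p_i (N p_i - 1) / (N - 1)

is exactly the probability that two samples drawn without replacement
share a pattern, D_j = 1 - C_j is the discriminating power, and
DL = 1 - sum_i p_i^2 its large-N limit, tied to D_j by the identity
D_j = N * DL / (N - 1).

``greedy_panel`` reproduces the maximisation-curve procedure: start from
the locus with the highest single-locus D, then repeatedly add whichever
remaining locus maximises the combined D, recording the cumulative D and
distinct-pattern count at every step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, BinaryGenotypeMatrix

#: pattern symbol for a locus that is MISSING in a combined profile
MISSING_PATTERN = "?"


@dataclass
class PatternProfile:
    """Distinct banding patterns and their counts under one scope."""

    scope: str
    N: int
    pattern_counts: dict[Hashable, int]

    def __post_init__(self) -> None:
        if sum(self.pattern_counts.values()) != self.N:
            raise ValueError("pattern counts must sum to N")

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return len(self.pattern_counts)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array(list(self.pattern_counts.values()), dtype=float) / self.N


def banding_patterns(matrix: BinaryGenotypeMatrix, locus: str) -> PatternProfile:
    """Pattern profile of one locus; samples with the locus MISSING excluded."""
    block = matrix.locus_calls(locus)
    scored = ~(block == MISSING).any(axis=1)
    if not scored.any():
        raise ValueError(f"locus {locus!r} is MISSING in every sample")
    counts: Counter = Counter(tuple(int(v) for v in row) for row in block[scored])
    return PatternProfile(locus, int(scored.sum()), dict(counts))


def confusion_probability(profile: PatternProfile) -> float:
    """P(two samples drawn without replacement share a pattern).

    Equals sum_i c_i (c_i - 1) / (N (N - 1)) exactly — the unordered-pair
    collision fraction.
    """
    if profile.N < 2:
        raise ValueError("confusion probability requires N >= 2")
    c = np.array(list(profile.pattern_counts.values()), dtype=float)
    n = profile.N
    return float(np.sum(c * (c - 1)) / (n * (n - 1)))


def discriminating_power(profile: PatternProfile) -> float:
    """D_j = 1 - C_j."""
    return 1.0 - confusion_probability(profile)


def dl_limit(profile: PatternProfile) -> float:
    """Large-sample limit DL = 1 - sum p_i^2 of the discriminating power."""
    p = profile.frequencies
    return 1.0 - float(np.sum(p**2))


def d_from_limit(dl: float, n: int) -> float:
    """Finite-sample D recovered from its limit: D = N * DL / (N - 1)."""
    if n < 2:
        raise ValueError("requires N >= 2")
    return n * dl / (n - 1)


def combined_profile(
    matrix: BinaryGenotypeMatrix, locus_subset: Sequence[str]
) -> PatternProfile:
    """Joint pattern profile over a locus subset.

    The combined pattern is the tuple of per-locus patterns; a MISSING
    locus contributes a sentinel symbol so every sample is retained and
    N stays constant across subsets (keeping cumulative D comparable).
    """
    loci = list(locus_subset)
    if not loci:
        raise ValueError("locus subset must be non-empty")
    keys: list[tuple] = [() for _ in range(matrix.n_samples)]
    for name in loci:
        block = matrix.locus_calls(name)
        miss = (block == MISSING).any(axis=1)
        for i in range(matrix.n_samples):
            part = MISSING_PATTERN if miss[i] else tuple(int(v) for v in block[i])
            keys[i] = keys[i] + (part,)
    counts = Counter(keys)
    return PatternProfile("+".join(loci), matrix.n_samples, dict(counts))


@dataclass
class PanelCurve:
    """Greedy locus order with the cumulative discrimination curve."""

    loci: list[str]
    cumulative_d: list[float]
    cumulative_patterns: list[int]
    plateau_index: int  # 1-based first step attaining the final pattern count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.loci) + 1),
                "locus": self.loci,
                "cumulative_d": self.cumulative_d,
                "cumulative_patterns": self.cumulative_patterns,
            }
        )


def greedy_panel(
    matrix: BinaryGenotypeMatrix, loci: Sequence[str] | None = None
) -> PanelCurve:
    """Sequentially add the locus maximising combined discriminating power.

    Step 1 picks the best single locus; each later step tries every
    remaining locus and keeps the one with the highest combined D (ties
    broken by input order).  Both recorded series are non-decreasing,
    since adding a locus only refines the pattern partition.
    """
    candidates = list(loci) if loci is not None else matrix.locus_names
    if not candidates:
        raise ValueError("need at least one locus")
    chosen: list[str] = []
    cum_d: list[float] = []
    cum_i: list[int] = []
    remaining = list(candidates)
    while remaining:
        best_name, best_d, best_i = None, -1.0, 0
        for name in remaining:
            prof = combined_profile(matrix, chosen + [name])
            d = discriminating_power(prof)
            if d > best_d:
                best_name, best_d, best_i = name, d, prof.I
        chosen.append(best_name)
        remaining.remove(best_name)
        cum_d.append(best_d)
        cum_i.append(best_i)
    final_i = cum_i[-1]
    plateau = next(i + 1 for i, v in enumerate(cum_i) if v == final_i)
    return PanelCurve(chosen, cum_d, cum_i, plateau)


def discrimination_table(matrix: BinaryGenotypeMatrix) -> pd.DataFrame:
    """Per-locus allele count, pattern count I, C, D and DL."""
    rows = []
    for loc in matrix.loci:
        prof = banding_patterns(matrix, loc.name)
        rows.append(
            {
                "marker": loc.name,
                "n_alleles": loc.n_alleles,
                "n_patterns": prof.I,
                "confusion": confusion_probability(prof),
                "discriminating_power": discriminating_power(prof),
                "dl_limit": dl_limit(prof),
            }
        )
    return pd.DataFrame(rows)
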