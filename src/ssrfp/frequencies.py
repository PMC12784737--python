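"""Allele-frequency estimation from dosage-ambiguous presence/absence data.

A hexaploid sample showing alleles {A, B} at a locus may carry any
dosage from 5A+1B to 1A+5B; binary scoring hides which.  Two estimators
are provided:

* :func:`simple_freq` — the uniform-split convention: a sample showing
  ``k`` distinct alleles credits ``ploidy / k`` copies to each.  Cheap,
  but biased (common alleles under-, rare alleles over-estimated).
* :func:`em_freq` — maximum likelihood under polysomic inheritance with
  partial selfing, via EM over the latent dosage.  The genotype prior is
  the mixture P(g) = (1-F) * multinomial(p) + F * [g monomorphic for a] * p_a
  with F = s/(2-s), the same model the synthetic generator draws from.

Both return an :class:`AlleleFrequencySet`: per-locus frequency vectors
with the allele-copy count n = ploidy x (non-missing samples) behind
each estimate.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, BinaryGenotypeMatrix
from .simulate import inbreeding_coefficient


@dataclass
class LocusFrequencies:
    locus: str
    allele_labels: tuple[int, ...]
    p: np.ndarray
    n: int
    method: str
    converged: bool | None = None
    n_iter: int | None = None
    loglik_trace: list[float] | None = None
    undefined: bool = False

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.allele_labels, map(float, self.p)))


@dataclass
class AlleleFrequencySet:
    method: str
    loci: dict[str, LocusFrequencies]

    def __getitem__(self, locus: str) -> LocusFrequencies:
        return self.loci[locus]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lf in self.loci.values():
            for a, pa in zip(lf.allele_labels, lf.p):
                rows.append(
                    {
                        "locus": lf.locus,
                        "allele": a,
                        "p": float(pa),
                        "n": lf.n,
                        "method": lf.method,
                        "converged": lf.converged,
                    }
                )
        return pd.DataFrame(rows)


def _locus_observations(
    matrix: BinaryGenotypeMatrix, locus: str
) -> tuple[Counter, int]:
    """Counter of distinct presence-index-tuples over non-missing samples."""
    block = matrix.locus_calls(locus)
    miss = (block == MISSING).any(axis=1)
    obs: Counter = Counter()
    for row in block[~miss]:
        obs[tuple(np.nonzero(row == 1)[0])] += 1
    return obs, int((~miss).sum())


def simple_freq(
    matrix: BinaryGenotypeMatrix, ploidy: int | None = None
) -> AlleleFrequencySet:
    """Uniform-split frequency estimate (each observed allele gets ploidy/k copies)."""
    ploidy = matrix.ploidy if ploidy is None else int(ploidy)
    out: dict[str, LocusFrequencies] = {}
    for loc in matrix.loci:
        obs, n_scored = _locus_observations(matrix, loc.name)
        k = loc.n_alleles
        if n_scored == 0:
            out[loc.name] = LocusFrequencies(
                loc.name, loc.allele_labels, np.full(k, np.nan), 0, "simple",
                undefined=True,
            )
            continue
        credits = np.zeros(k)
        for alleles, count in obs.items():
            if alleles:
                credits[list(alleles)] += count * ploidy / len(alleles)
        if credits.sum() == 0:  # scored lanes but no bands anywhere
            out[loc.name] = LocusFrequencies(
                loc.name, loc.allele_labels, np.full(k, np.nan), 0, "simple",
                undefined=True,
            )
            continue
        out[loc.name] = LocusFrequencies(
            loc.name, loc.allele_labels, credits / credits.sum(),
            ploidy * n_scored, "simple",
        )
    return AlleleFrequencySet("simple", out)


@lru_cache(maxsize=None)
def _compositions(total: int, parts: int) -> tuple[tuple[int, ...], ...]:
    """All tuples of ``parts`` positive integers summing to ``total``."""
    if parts == 1:
        return ((total,),)
    out = []
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            out.append((first,) + rest)
    return tuple(out)


@lru_cache(maxsize=None)
def _multinomial_coef(counts: tuple[int, ...]) -> float:
    n = sum(counts)
    c = math.factorial(n)
    for x in counts:
        c //= math.factorial(x)
    return float(c)


def genotype_probability(
    multiset: Sequence[int],
    p: Mapping[int, float],
    selfing_rate: float,
    ploidy: int | None = None,
) -> float:
    """Probability of a dosage genotype under polysomic inheritance with selfing.

    ``multiset`` lists allele labels with repetition (size = ploidy);
    ``p`` maps allele label -> frequency.  The model is the inbreeding
    mixture described in the module docstring; at ``selfing_rate=0`` it
    is the plain multinomial.
    """
    multiset = tuple(multiset)
    if ploidy is not None and len(multiset) != ploidy:
        raise ValueError(f"genotype has {len(multiset)} copies, expected {ploidy}")
    missing = [a for a in multiset if a not in p]
    if missing:
        raise KeyError(f"alleles {sorted(set(missing))} absent from frequency vector")
    counts = Counter(multiset)
    F = inbreeding_coefficient(selfing_rate)
    pm = _multinomial_coef(tuple(sorted(counts.values())))
    for a, c in counts.items():
        pm *= p[a] ** c
    out = (1.0 - F) * pm
    if len(counts) == 1:
        (a,) = counts
        out += F * p[a]
    return out


def _presence_set_likelihood_terms(
    alleles: tuple[int, ...], p: np.ndarray, F: float, ploidy: int
) -> tuple[float, np.ndarray]:
    """Likelihood of one observed presence set and expected founder-draw counts.

    Enumerates every dosage genotype compatible with the presence set
    (compositions of ``ploidy`` over the observed alleles, each >= 1)
    plus, for singleton sets, the inbred branch.  Returns (likelihood,
    expected founder-draw count per allele index of the full vector).

    "Founder draws" are the independent draws from p that generated the
    genotype: ``ploidy`` of them for the outbred branch, one for the
    inbred branch.  Using these as the EM weights makes the M-step exact
    for the mixture, so the observed-data log-likelihood is monotone.
    """
    k = len(alleles)
    pa = p[list(alleles)]
    lik = 0.0
    counts = np.zeros(p.size)
    for comp in _compositions(ploidy, k):
        w = (1.0 - F) * _multinomial_coef(tuple(sorted(comp))) * float(
            np.prod(pa ** np.asarray(comp))
        )
        lik += w
        counts[list(alleles)] += w * np.asarray(comp, dtype=float)
    if k == 1:
        w = F * pa[0]
        lik += w
        counts[alleles[0]] += w  # one founder draw, not ploidy copies
    return lik, counts


def em_freq(
    matrix: BinaryGenotypeMatrix,
    ploidy: int | None = None,
    selfing_rate: float = 0.07,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> AlleleFrequencySet:
    """EM maximum-likelihood allele frequencies under polysomic inheritance.

    Initialised from :func:`simple_freq`; iterates E (posterior over
    latent dosage genotypes per sample-locus) and M (normalised expected
    founder-draw counts) until the L-inf change in p drops below ``tol``
    or ``max_iter`` is reached.  Non-convergence warns and sets
    ``converged=False``.  The per-locus observed-data log-likelihood
    trace is kept on the result for diagnostics.
    """
    ploidy = matrix.ploidy if ploidy is None else int(ploidy)
    if not 0.0 <= selfing_rate < 1.0:
        raise ValueError("selfing_rate must be in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    F = inbreeding_coefficient(selfing_rate)
    init = simple_freq(matrix, ploidy)
    out: dict[str, LocusFrequencies] = {}
    for loc in matrix.loci:
        start = init[loc.name]
        if start.undefined:
            out[loc.name] = LocusFrequencies(
                loc.name, loc.allele_labels, start.p.copy(), 0, "em", undefined=True
            )
            continue
        obs, n_scored = _locus_observations(matrix, loc.name)
        obs = Counter({a: c for a, c in obs.items() if a})
        p = start.p.copy()
        # zero-frequency guard: alleles never observed stay at 0, which is
        # their MLE; observed alleles keep strictly positive mass from init
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            loglik = 0.0
            expected = np.zeros_like(p)
            for alleles, count in obs.items():
                lik, cnt = _presence_set_likelihood_terms(alleles, p, F, ploidy)
                loglik += count * math.log(lik)
                expected += count * cnt / lik
            trace.append(loglik)
            p_new = expected / expected.sum()
            delta = float(np.max(np.abs(p_new - p)))
            p = p_new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"em_freq: locus {loc.name!r} did not converge in {max_iter} "
                f"iterations", stacklevel=2,
            )
        out[loc.name] = LocusFrequencies(
            loc.name, loc.allele_labels, p, ploidy * n_scored, "em",
            converged=converged, n_iter=it, loglik_trace=trace,
        )
    return AlleleFrequencySet("em", out)


def write_frequency_table(
    simple: AlleleFrequencySet, em: AlleleFrequencySet, path: str | Path
) -> pd.DataFrame:
    """CSV: locus, allele, p_simple, p_em, n, converged. Returns the frame."""
    rows = []
    for locus, lf_s in simple.loci.items():
        lf_e = em.loci[locus]
        for a, ps, pe in zip(lf_s.allele_labels, lf_s.p, lf_e.p):
            rows.append(
                {
                    "locus": locus,
                    "allele": a,
                    "p_simple": float(ps),
                    "p_em": float(pe),
                    "n": lf_s.n,
                    "converged": lf_e.converged,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
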