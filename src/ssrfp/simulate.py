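"""Synthetic hexaploid SSR datasets with known truth.

The generator emulates the structure of a binary-scored SSR study of a
clonal, partially selfing hexaploid crop: per-locus allele frequencies
drawn from a symmetric Dirichlet, founder genotypes of ``ploidy`` allele
copies drawn under polysomic inheritance with equilibrium inbreeding
F = s/(2-s), clonal copies of each founder, collapse of dosage to
presence/absence, and per-allele scoring noise (dropout, false alleles,
whole-locus failures).  Ground truth (frequencies, founder genotypes,
clone groups) is retained so estimators and duplicate detection can be
scored against it.

Inbreeding model: with probability F an individual's locus is fully
identical-by-descent (all copies are one allele drawn from p), otherwise
all copies are independent draws from p.  This is the simplest
exchangeable model with the right limits (s=0 -> multinomial; s -> 1 ->
all copies identical with probability 1) and is shared verbatim by the
EM frequency estimator, so parameter recovery is well-posed.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MISSING, BinaryGenotypeMatrix, LocusDefinition, SampleRecord


def inbreeding_coefficient(selfing_rate: float) -> float:
    """Equilibrium inbreeding coefficient F = s/(2-s) under partial selfing."""
    if not 0.0 <= selfing_rate < 1.0:
        raise ValueError("selfing_rate must be in [0, 1)")
    return selfing_rate / (2.0 - selfing_rate)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real panel: 19 loci with 3-12 alleles each,
    hexaploid samples, selfing rate 0.07, clone groups of 2-4 copies.
    Scoring-noise defaults (dropout 0.01, false allele 0.005, locus
    missing 0.02) are generator choices at levels typical of careful
    manual gel scoring.
    """

    n_loci: int = 19
    min_alleles: int = 3
    max_alleles: int = 12
    dirichlet_concentration: float = 1.0
    ploidy: int = 6
    n_founders: int = 20
    min_clones: int = 2
    max_clones: int = 4
    selfing_rate: float = 0.07
    dropout_rate: float = 0.01
    false_allele_rate: float = 0.005
    locus_missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if not 1 <= self.min_alleles <= self.max_alleles:
            raise ValueError("need 1 <= min_alleles <= max_alleles")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        for name in ("selfing_rate", "dropout_rate", "false_allele_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.locus_missing_rate <= 1.0:
            raise ValueError("locus_missing_rate must be in [0, 1]")
        if not 1 <= self.min_clones <= self.max_clones:
            raise ValueError("need 1 <= min_clones <= max_clones")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated matrix."""

    true_frequencies: dict[str, np.ndarray]
    founder_genotypes: dict[str, dict[str, tuple[int, ...]]]
    clone_group: dict[str, str]
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "true_frequencies": {
                k: list(map(float, v)) for k, v in self.true_frequencies.items()
            },
            "founder_genotypes": {
                f: {loc: list(g) for loc, g in per.items()}
                for f, per in self.founder_genotypes.items()
            },
            "clone_group": self.clone_group,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def draw_locus_frequencies(
    config: SimulationConfig, locus_index: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Symmetric-Dirichlet allele-frequency vector for one locus.

    The allele count is drawn uniformly from the configured range; the
    returned vector is non-negative and sums to 1.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, locus_index))
    k = int(rng.integers(config.min_alleles, config.max_alleles + 1))
    p = rng.dirichlet(np.full(k, config.dirichlet_concentration))
    return p / p.sum()


def simulate_founder_genotype(
    freqs: np.ndarray, ploidy: int, selfing_rate: float, rng: np.random.Generator
) -> tuple[int, ...]:
    """Multiset of ``ploidy`` allele copies (as indices into ``freqs``).

    With probability F = s/(2-s) every copy reuses a single founder draw
    from ``freqs`` (fully inbred locus); otherwise copies are iid draws.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0 or np.any(freqs < 0):
        raise ValueError("freqs must be a non-negative 1-D vector")
    p = freqs / freqs.sum()
    if rng.random() < inbreeding_coefficient(selfing_rate):
        a = int(rng.choice(p.size, p=p))
        return (a,) * ploidy
    return tuple(sorted(int(a) for a in rng.choice(p.size, size=ploidy, p=p)))


def phenotype_from_genotype(multiset: tuple[int, ...]) -> tuple[int, ...]:
    """Collapse a dosage genotype to the set of distinct alleles observed."""
    if not multiset:
        raise ValueError("empty genotype")
    return tuple(sorted(set(multiset)))


def apply_errors(
    matrix: BinaryGenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> BinaryGenotypeMatrix:
    """Corrupt a matrix with per-allele flips and whole-locus failures.

    Each present cell drops out (1 -> 0) with ``dropout_rate``; each
    absent cell gains a false allele (0 -> 1) with ``false_allele_rate``;
    each sample-locus goes wholly MISSING with ``locus_missing_rate``.
    A scored locus is never left empty: if dropout removes every band,
    one original allele is re-instated (a lane with no bands at all would
    have been scored as failed, i.e. MISSING).
    """
    calls = matrix.calls.copy()
    for loc in matrix.loci:
        cols = matrix.locus_columns(loc.name)
        block = calls[:, cols]
        scored = ~(block == MISSING).any(axis=1)
        orig = block.copy()
        drop = (block == 1) & (rng.random(block.shape) < config.dropout_rate)
        gain = (block == 0) & (rng.random(block.shape) < config.false_allele_rate)
        block = np.where(drop, 0, block)
        block = np.where(gain, 1, block)
        # re-instate one original allele if dropout emptied a scored locus
        emptied = scored & ((block == 1).sum(axis=1) == 0)
        for i in np.nonzero(emptied)[0]:
            present = np.nonzero(orig[i] == 1)[0]
            if present.size:
                block[i, rng.choice(present)] = 1
        # false alleles may not push a lane past the ploidy cap: drop excess
        # gained bands (a scorer would reject such a lane as artefactual)
        over = scored & ((block == 1).sum(axis=1) > matrix.ploidy)
        for i in np.nonzero(over)[0]:
            gained = np.nonzero(gain[i] & (block[i] == 1))[0]
            excess = int((block[i] == 1).sum()) - matrix.ploidy
            for j in rng.choice(gained, size=excess, replace=False):
                block[i, j] = 0
        fail = scored & (rng.random(len(scored)) < config.locus_missing_rate)
        block[fail] = MISSING
        calls[:, cols] = block
    return BinaryGenotypeMatrix(
        list(matrix.samples), list(matrix.loci), calls, matrix.ploidy
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[BinaryGenotypeMatrix, SimulationTruth]:
    """Full synthetic dataset: clonal copies of founders plus scoring noise.

    All randomness flows from one generator seeded by ``config.seed`` in
    a fixed order (frequencies, founders, clone counts, errors), so a
    given config is byte-reproducible.
    """
    rng = np.random.default_rng(config.seed)

    freqs: dict[str, np.ndarray] = {}
    loci: list[LocusDefinition] = []
    for j in range(config.n_loci):
        p = draw_locus_frequencies(config, j, rng)
        name = f"L{j + 1:02d}"
        # allele size labels: arbitrary distinct bp values, 2 bp ladder
        loci.append(LocusDefinition(name, tuple(100 + 2 * a for a in range(p.size))))
        freqs[name] = p

    founder_genotypes: dict[str, dict[str, tuple[int, ...]]] = {}
    founder_phenotypes: dict[str, dict[str, tuple[int, ...]]] = {}
    for f in range(config.n_founders):
        fid = f"F{f + 1:03d}"
        per_g: dict[str, tuple[int, ...]] = {}
        per_ph: dict[str, tuple[int, ...]] = {}
        for loc in loci:
            g = simulate_founder_genotype(
                freqs[loc.name], config.ploidy, config.selfing_rate, rng
            )
            per_g[loc.name] = g
            per_ph[loc.name] = phenotype_from_genotype(g)
        founder_genotypes[fid] = per_g
        founder_phenotypes[fid] = per_ph

    samples: list[SampleRecord] = []
    clone_group: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for fid in founder_genotypes:
        n_clones = int(rng.integers(config.min_clones, config.max_clones + 1))
        for c in range(n_clones):
            sid = f"{fid}_c{c + 1}"
            samples.append(SampleRecord(sid, "study"))
            clone_group[sid] = fid
            row = np.zeros(sum(l.n_alleles for l in loci), dtype=np.int8)
            col0 = 0
            for loc in loci:
                for a in founder_phenotypes[fid][loc.name]:
                    row[col0 + a] = 1
                col0 += loc.n_alleles
            rows.append(row)

    clean = BinaryGenotypeMatrix(samples, loci, np.vstack(rows), config.ploidy)
    noisy = apply_errors(clean, config, rng)
    truth = SimulationTruth(freqs, founder_genotypes, clone_group, config)
    return noisy, truth


def true_presence_frequencies(truth: SimulationTruth) -> dict[str, np.ndarray]:
    """Convenience: the generating frequency vectors, keyed by locus."""
    return dict(truth.true_frequencies)
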