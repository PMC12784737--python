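"""Data model and I/O for binary-scored polyploid SSR genotype matrices.

Polyploid SSR gels cannot resolve allele dosage, so each allele (fragment
size in bp) is scored per sample as present (1) or absent (0); a failed
locus is coded 9 for every allele of that locus.  The central container,
:class:`BinaryGenotypeMatrix`, keeps samples x allele-columns calls with
the columns grouped into loci, and enforces the scoring invariants:
missingness is locus-level, and no sample may show more distinct alleles
at a locus than its ploidy.

The on-disk format is a small CSV dialect: header row 1 carries the locus
name above each of its allele columns, header row 2 the allele size label
(bp), and each data row is ``sample_id, group, 0/1/9 cells``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = 9
GROUPS = ("study", "reference")


class GenotypeParseError(ValueError):
    """Malformed genotype table (bad header or cell); names the line."""


class GenotypeValidationError(ValueError):
    """Structurally parseable table that violates a scoring invariant."""


@dataclass(frozen=True)
class LocusDefinition:
    """One SSR locus and the allele size labels (bp) scored for it."""

    name: str
    allele_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.allele_labels:
            raise ValueError(f"locus {self.name!r} has no alleles")
        labels = tuple(int(a) for a in self.allele_labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")
        object.__setattr__(self, "allele_labels", tuple(sorted(labels)))

    @property
    def n_alleles(self) -> int:
        return len(self.allele_labels)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str = "study"
    display_name: str = ""
    biological_status: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown sample group {self.group!r}")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.sample_id)


@dataclass(frozen=True)
class Violation:
    """One invariant violation; reported, never raised, by :func:`validate`."""

    sample_id: str
    locus: str
    rule: str
    message: str


class BinaryGenotypeMatrix:
    """Samples x allele-columns presence/absence calls grouped into loci.

    ``calls[i, j]`` is 0 (absent), 1 (present) or 9 (missing) for sample
    ``i`` at allele column ``j``.  Columns are laid out locus by locus in
    the order of ``loci``, alleles ascending by size within each locus.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        loci: Sequence[LocusDefinition],
        calls: np.ndarray,
        ploidy: int = 6,
    ) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        self.ploidy = int(ploidy)
        calls = np.asarray(calls, dtype=np.int8)
        n_cols = sum(l.n_alleles for l in self.loci)
        if calls.shape != (len(self.samples), n_cols):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(self.samples)}, {n_cols}) implied by samples/loci"
            )
        bad = ~np.isin(calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must contain only 0, 1 or 9")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in matrix")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus name in matrix")
        self.calls = calls
        # column slices per locus, in layout order
        self._locus_cols: dict[str, np.ndarray] = {}
        start = 0
        for loc in self.loci:
            self._locus_cols[loc.name] = np.arange(start, start + loc.n_alleles)
            start += loc.n_alleles

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_allele_columns(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> LocusDefinition:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"unknown locus {name!r}")

    def locus_columns(self, name: str) -> np.ndarray:
        if name not in self._locus_cols:
            raise KeyError(f"unknown locus {name!r}")
        return self._locus_cols[name]

    def locus_calls(self, name: str) -> np.ndarray:
        """(n_samples, n_alleles) view of calls for one locus."""
        return self.calls[:, self.locus_columns(name)]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def locus_missing_mask(self) -> np.ndarray:
        """(n_samples, n_loci) bool: True where the sample-locus is MISSING."""
        out = np.zeros((self.n_samples, len(self.loci)), dtype=bool)
        for k, loc in enumerate(self.loci):
            out[:, k] = (self.locus_calls(loc.name) == MISSING).any(axis=1)
        return out

    def presence_set(self, sample_id: str, locus: str) -> tuple[int, ...] | None:
        """Distinct allele labels present for one sample-locus; None if MISSING."""
        i = self.sample_index(sample_id)
        loc = self.locus(locus)
        row = self.locus_calls(locus)[i]
        if (row == MISSING).any():
            return None
        return tuple(a for a, c in zip(loc.allele_labels, row) if c == 1)

    def copy(self) -> "BinaryGenotypeMatrix":
        return BinaryGenotypeMatrix(
            list(self.samples), list(self.loci), self.calls.copy(), self.ploidy
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryGenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and self.ploidy == other.ploidy
            and np.array_equal(self.calls, other.calls)
        )


# -- validation ----------------------------------------------------------


def validate(matrix: BinaryGenotypeMatrix) -> list[Violation]:
    """Report every scoring-invariant violation (empty list == valid).

    Rules checked per sample-locus: ``partial_missing`` (some but not all
    allele cells coded 9) and ``over_ploidy`` (more present alleles than
    the ploidy).  Structural problems (shape, cell domain, duplicate ids)
    are rejected at construction time instead.
    """
    out: list[Violation] = []
    for loc in matrix.loci:
        block = matrix.locus_calls(loc.name)
        miss = block == MISSING
        partial = miss.any(axis=1) & ~miss.all(axis=1)
        counts = (block == 1).sum(axis=1)
        for i in np.nonzero(partial)[0]:
            out.append(
                Violation(
                    matrix.samples[i].sample_id,
                    loc.name,
                    "partial_missing",
                    "some but not all allele cells of the locus are coded 9",
                )
            )
        over = ~miss.any(axis=1) & (counts > matrix.ploidy)
        for i in np.nonzero(over)[0]:
            out.append(
                Violation(
                    matrix.samples[i].sample_id,
                    loc.name,
                    "over_ploidy",
                    f"{counts[i]} present alleles exceed ploidy {matrix.ploidy}",
                )
            )
    return out


def _raise_if_invalid(matrix: BinaryGenotypeMatrix, where: str) -> None:
    violations = validate(matrix)
    if violations:
        v = violations[0]
        raise GenotypeValidationError(
            f"{where}: {len(violations)} invariant violation(s); first: "
            f"sample {v.sample_id!r} locus {v.locus!r}: {v.message}"
        )


# -- CSV dialect ---------------------------------------------------------


def read_genotype_table(
    path: str | Path, dialect_config: Mapping | None = None
) -> BinaryGenotypeMatrix:
    """Read the genotype CSV dialect into a validated matrix.

    ``dialect_config`` keys (all optional): ``ploidy`` (default 6) and
    ``missing_code`` (default 9; remapped to 9 internally).
    """
    cfg = dict(dialect_config or {})
    ploidy = int(cfg.get("ploidy", 6))
    missing_code = int(cfg.get("missing_code", MISSING))
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise GenotypeParseError(f"{path}: need two header rows, got {len(rows)}")
    locus_row, size_row = rows[0], rows[1]
    if len(locus_row) != len(size_row):
        raise GenotypeParseError(f"{path} line 2: header rows differ in length")
    if len(locus_row) < 3:
        raise GenotypeParseError(f"{path} line 1: no allele columns")

    # group consecutive columns by locus name (cols 0-1 are sample_id, group)
    loci: list[LocusDefinition] = []
    col_names = locus_row[2:]
    col_sizes = size_row[2:]
    seen: set[str] = set()
    i = 0
    while i < len(col_names):
        name = col_names[i].strip()
        if not name:
            raise GenotypeParseError(f"{path} line 1: empty locus name at column {i + 3}")
        if name in seen:
            raise GenotypeParseError(
                f"{path} line 1: locus {name!r} appears in non-contiguous column blocks"
            )
        seen.add(name)
        labels = []
        while i < len(col_names) and col_names[i].strip() == name:
            try:
                labels.append(int(col_sizes[i]))
            except ValueError:
                raise GenotypeParseError(
                    f"{path} line 2: allele size {col_sizes[i]!r} at column "
                    f"{i + 3} is not an integer"
                ) from None
            i += 1
        try:
            loci.append(LocusDefinition(name, tuple(labels)))
        except ValueError as exc:
            raise GenotypeParseError(f"{path} line 2: {exc}") from None

    n_cols = len(col_names)
    samples: list[SampleRecord] = []
    calls = []
    for lineno, row in enumerate(rows[2:], start=3):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) != n_cols + 2:
            raise GenotypeParseError(
                f"{path} line {lineno}: expected {n_cols + 2} fields, got {len(row)}"
            )
        group = row[1].strip() or "study"
        try:
            samples.append(SampleRecord(row[0].strip(), group))
        except ValueError as exc:
            raise GenotypeParseError(f"{path} line {lineno}: {exc}") from None
        vals = []
        for j, cell in enumerate(row[2:]):
            try:
                v = int(cell)
            except ValueError:
                raise GenotypeParseError(
                    f"{path} line {lineno}: cell {cell!r} at column {j + 3} "
                    "is not 0/1/9"
                ) from None
            if v == missing_code:
                v = MISSING
            if v not in (0, 1, MISSING):
                raise GenotypeParseError(
                    f"{path} line {lineno}: cell value {v} at column {j + 3} "
                    "is not 0/1/9"
                )
            vals.append(v)
        calls.append(vals)

    matrix = BinaryGenotypeMatrix(
        samples, loci, np.asarray(calls, dtype=np.int8).reshape(len(samples), n_cols),
        ploidy=ploidy,
    )
    _raise_if_invalid(matrix, str(path))
    return matrix


def write_genotype_table(matrix: BinaryGenotypeMatrix, path: str | Path) -> None:
    """Write the genotype CSV dialect; round-trips through read_genotype_table."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        locus_row = ["sample_id", "group"]
        size_row = ["", ""]
        for loc in matrix.loci:
            locus_row.extend([loc.name] * loc.n_alleles)
            size_row.extend(str(a) for a in loc.allele_labels)
        w.writerow(locus_row)
        w.writerow(size_row)
        for i, s in enumerate(matrix.samples):
            w.writerow([s.sample_id, s.group] + [str(v) for v in matrix.calls[i]])


# -- panel merge and subsetting -------------------------------------------


def merge_panels(
    reference: BinaryGenotypeMatrix,
    query: BinaryGenotypeMatrix,
    unshared_loci: str = "keep",
) -> BinaryGenotypeMatrix:
    """Merge a query panel into a reference panel on shared locus names.

    Allele columns become the per-locus union, matched by exact size
    label.  A sample whose source panel lacks an allele column scored
    elsewhere receives 0 there when its locus is scored (presence/absence
    scoring registers all detected bands, so unreported sizes are
    absences) and MISSING when the locus is MISSING.  ``unshared_loci``
    controls loci present in only one panel: ``"keep"`` retains them with
    all-MISSING calls for the other panel, ``"drop"`` removes them.
    """
    if unshared_loci not in ("keep", "drop"):
        raise ValueError("unshared_loci must be 'keep' or 'drop'")
    if reference.ploidy != query.ploidy:
        raise ValueError(
            f"ploidy mismatch: reference {reference.ploidy}, query {query.ploidy}"
        )
    dup = set(reference.sample_ids) & set(query.sample_ids)
    if dup:
        raise ValueError(f"duplicate sample_id across panels: {sorted(dup)}")

    ref_names = set(reference.locus_names)
    qry_names = set(query.locus_names)
    merged_names = list(reference.locus_names)
    merged_names += [n for n in query.locus_names if n not in ref_names]
    if unshared_loci == "drop":
        merged_names = [n for n in merged_names if n in ref_names and n in qry_names]

    merged_loci = []
    for name in merged_names:
        labels: set[int] = set()
        if name in ref_names:
            labels |= set(reference.locus(name).allele_labels)
        if name in qry_names:
            labels |= set(query.locus(name).allele_labels)
        merged_loci.append(LocusDefinition(name, tuple(sorted(labels))))

    samples = list(reference.samples) + list(query.samples)
    n = len(samples)
    n_cols = sum(l.n_alleles for l in merged_loci)
    calls = np.zeros((n, n_cols), dtype=np.int8)
    col0 = 0
    for loc in merged_loci:
        for panel, row_off in ((reference, 0), (query, reference.n_samples)):
            rows = slice(row_off, row_off + panel.n_samples)
            if loc.name not in panel._locus_cols:
                calls[rows, col0 : col0 + loc.n_alleles] = MISSING
                continue
            src = panel.locus_calls(loc.name)
            src_labels = panel.locus(loc.name).allele_labels
            pos = {a: j for j, a in enumerate(loc.allele_labels)}
            block = np.zeros((panel.n_samples, loc.n_alleles), dtype=np.int8)
            for j, a in enumerate(src_labels):
                block[:, pos[a]] = src[:, j]
            miss = (src == MISSING).any(axis=1)
            block[miss] = MISSING
            calls[rows, col0 : col0 + loc.n_alleles] = block
        col0 += loc.n_alleles

    merged = BinaryGenotypeMatrix(samples, merged_loci, calls, reference.ploidy)
    _raise_if_invalid(merged, "merge_panels")
    return merged


def subset(
    matrix: BinaryGenotypeMatrix,
    sample_ids: Iterable[str] | None = None,
    locus_names: Iterable[str] | None = None,
) -> BinaryGenotypeMatrix:
    """Restrict to the named samples/loci, preserving the matrix's order."""
    if sample_ids is None:
        keep_samples = set(matrix.sample_ids)
    else:
        keep_samples = set(sample_ids)
        unknown = keep_samples - set(matrix.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample ids: {sorted(unknown)}")
    if locus_names is None:
        keep_loci = set(matrix.locus_names)
    else:
        keep_loci = set(locus_names)
        unknown = keep_loci - set(matrix.locus_names)
        if unknown:
            raise KeyError(f"unknown loci: {sorted(unknown)}")

    rows = [i for i, s in enumerate(matrix.samples) if s.sample_id in keep_samples]
    cols: list[int] = []
    loci = []
    for loc in matrix.loci:
        if loc.name in keep_loci:
            loci.append(loc)
            cols.extend(matrix.locus_columns(loc.name))
    return BinaryGenotypeMatrix(
        [matrix.samples[i] for i in rows],
        loci,
        matrix.calls[np.ix_(rows, cols)],
        matrix.ploidy,
    )


def restrict_alleles(
    matrix: BinaryGenotypeMatrix, loci: Sequence[LocusDefinition]
) -> BinaryGenotypeMatrix:
    """Project onto another panel's allele columns (drop extra alleles)."""
    sub = subset(matrix, locus_names=[l.name for l in loci])
    cols = []
    new_loci = []
    for loc in loci:
        have = sub.locus(loc.name)
        base = sub.locus_columns(loc.name)
        idx = {a: base[j] for j, a in enumerate(have.allele_labels)}
        missing = [a for a in loc.allele_labels if a not in idx]
        if missing:
            raise KeyError(f"locus {loc.name!r}: allele labels {missing} not present")
        cols.extend(idx[a] for a in loc.allele_labels)
        new_loci.append(loc)
    return BinaryGenotypeMatrix(
        list(sub.samples), new_loci, sub.calls[:, cols], sub.ploidy
    )
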