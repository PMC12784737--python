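"""Jaccard dissimilarity, neighbor-joining trees with locus bootstrap,
threshold-based duplicate detection, and ROC evaluation.

Binary allele presences are treated as independent dominant markers:
for a pair of samples restricted to the allele columns of loci scored in
both, d = 1 - a / (a + b + c) with a the shared presences and b + c the
mismatches.  Trees use the unweighted Saitou-Nei neighbor-joining
agglomeration (via scikit-bio); branch support comes from resampling
whole loci with replacement, so the within-locus dependence between
allele columns is preserved.  Pairs below a dissimilarity threshold
(strictly, default 0.05) are flagged as candidate clonal duplicates and
grouped by single linkage over the flagged pairs.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM, TreeNode
from skbio.tree import nj as _skbio_nj

from .io import MISSING, BinaryGenotypeMatrix


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities; NaN marks undefined pairs."""

    ids: list[str]
    d: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_phylip(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.d):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{name}\t{cells}\n")


def _pairwise_jaccard(present: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Jaccard distances over per-sample valid (co-scored) columns."""
    n = present.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        vi, xi = valid[i], present[i]
        both = valid[i + 1 :] & vi
        a = ((present[i + 1 :] & xi) & both).sum(axis=1)
        union = ((present[i + 1 :] | xi) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = 1.0 - np.where(union > 0, a / np.where(union > 0, union, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def _presence_and_validity(
    matrix: BinaryGenotypeMatrix, locus_indices: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(present, valid) boolean column matrices, optionally locus-resampled."""
    loci = matrix.loci
    indices = range(len(loci)) if locus_indices is None else locus_indices
    blocks_p, blocks_v = [], []
    for k in indices:
        block = matrix.locus_calls(loci[k].name)
        miss = (block == MISSING).any(axis=1)
        blocks_p.append(block == 1)
        blocks_v.append(np.repeat(~miss[:, None], block.shape[1], axis=1))
    return np.hstack(blocks_p), np.hstack(blocks_v)


def jaccard_matrix(matrix: BinaryGenotypeMatrix) -> DissimilarityMatrix:
    """Pairwise Jaccard dissimilarity with locus-level missing-data masking.

    Each pair is restricted to allele columns of loci scored in both
    samples; a pair with no co-scored locus gets NaN and is listed in
    ``undefined_pairs``.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    present, valid = _presence_and_validity(matrix)
    d = _pairwise_jaccard(present, valid)
    ids = matrix.sample_ids
    undefined = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if math.isnan(d[i, j])
    ]
    return DissimilarityMatrix(ids, d, undefined)


# -- trees ----------------------------------------------------------------


def nj_tree(D: DissimilarityMatrix, clamp_negative: bool = False) -> TreeNode:
    """Unrooted Saitou-Nei neighbor-joining tree.

    NJ can produce negative branch lengths; they are retained by default
    (``clamp_negative=True`` zeroes them).  Undefined distances are an
    error — resolve them before tree building.
    """
    if len(D.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    if np.isnan(D.d).any():
        raise ValueError(
            f"distance matrix has undefined pairs: {D.undefined_pairs[:3]}"
        )
    return _skbio_nj(_SkbioDM(D.d, D.ids), neg_as_zero=clamp_negative)


def to_newick(tree: TreeNode) -> str:
    """Newick text with branch lengths; internal labels carry support."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def parse_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")


def _bipartitions(tree: TreeNode) -> dict[int, frozenset]:
    """Canonical non-trivial bipartition per internal node id.

    A bipartition is keyed by its canonical side: the smaller of the two
    leaf-name sets (ties by sorted order), making it stable under
    rerooting.
    """
    tips = frozenset(t.name for t in tree.tips())
    out: dict[int, frozenset] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        comp = tips - side
        if len(side) < 2 or len(comp) < 2:
            continue
        canon = min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))
        out[id(node)] = canon
    return out


def bootstrap_support(
    matrix: BinaryGenotypeMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    clamp_negative: bool = False,
) -> TreeNode:
    """Reference NJ tree with locus-bootstrap support on internal edges.

    Loci are resampled with replacement (allele columns travel with
    their locus); each replicate's Jaccard+NJ tree votes for the
    reference tree's internal bipartitions.  Support (percent of
    replicates, in [0, 100]) is stored on internal nodes as ``support``
    and as the node name, so Newick export carries it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref_D = jaccard_matrix(matrix)
    ref = nj_tree(ref_D, clamp_negative=clamp_negative)
    ref_parts = _bipartitions(ref)
    votes = {part: 0 for part in ref_parts.values()}

    rng = np.random.default_rng(seed)
    n_loci = len(matrix.loci)
    ids = matrix.sample_ids
    for _ in range(n_reps):
        pick = rng.integers(0, n_loci, size=n_loci)
        present, valid = _presence_and_validity(matrix, pick)
        d = _pairwise_jaccard(present, valid)
        if np.isnan(d).any():  # replicate dropped a pair's co-scored loci
            continue
        rep = _skbio_nj(_SkbioDM(d, ids), neg_as_zero=clamp_negative)
        rep_parts = set(_bipartitions(rep).values())
        for part in votes:
            if part in rep_parts:
                votes[part] += 1

    for node in ref.non_tips(include_self=False):
        part = ref_parts.get(id(node))
        if part is None:
            continue
        # scikit-bio's newick writer emits .support as the internal label
        node.support = round(100.0 * votes[part] / n_reps, 1)
    return ref


def node_support(node: TreeNode) -> float | None:
    """Bootstrap support of an internal node, also after a Newick round-trip."""
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.name is not None:
        try:
            return float(node.name)
        except ValueError:
            return None
    return None


# -- duplicates -----------------------------------------------------------


@dataclass
class LocusComparison:
    locus: str
    comparable: bool
    match: bool
    differing_alleles: tuple[int, ...]


@dataclass
class ProfileComparison:
    sample_a: str
    sample_b: str
    loci: list[LocusComparison]

    @property
    def mismatching_loci(self) -> list[str]:
        return [c.locus for c in self.loci if c.comparable and not c.match]

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatching_loci)


def verify_profiles(
    matrix: BinaryGenotypeMatrix, pair: tuple[str, str]
) -> ProfileComparison:
    """Per-locus allele-profile comparison of one candidate duplicate pair."""
    a, b = pair
    ia, ib = matrix.sample_index(a), matrix.sample_index(b)
    loci: list[LocusComparison] = []
    for loc in matrix.loci:
        block = matrix.locus_calls(loc.name)
        ra, rb = block[ia], block[ib]
        if (ra == MISSING).any() or (rb == MISSING).any():
            loci.append(LocusComparison(loc.name, False, False, ()))
            continue
        diff = tuple(
            label
            for label, va, vb in zip(loc.allele_labels, ra, rb)
            if va != vb
        )
        loci.append(LocusComparison(loc.name, True, not diff, diff))
    return ProfileComparison(a, b, loci)


@dataclass
class DuplicatePair:
    sample_a: str
    sample_b: str
    d: float
    mismatch_count: int | None = None
    mismatching_loci: list[str] | None = None


@dataclass
class DuplicateReport:
    threshold: float
    pairs: list[DuplicatePair]
    groups: list[list[str]]
    excluded_pairs: list[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_a": p.sample_a,
                    "sample_b": p.sample_b,
                    "d": p.d,
                    "mismatch_count": p.mismatch_count,
                    "mismatching_loci": ";".join(p.mismatching_loci or [])
                    if p.mismatching_loci is not None
                    else None,
                }
                for p in self.pairs
            ]
        )

    def to_json_payload(self) -> dict:
        return {
            "threshold": self.threshold,
            "pairs": [vars(p) for p in self.pairs],
            "groups": self.groups,
            "excluded_pairs": [list(t) for t in self.excluded_pairs],
        }


def find_duplicates(
    D: DissimilarityMatrix,
    threshold: float = 0.05,
    matrix: BinaryGenotypeMatrix | None = None,
) -> DuplicateReport:
    """Flag pairs with d strictly below the threshold; group by single linkage.

    Groups are the connected components of the flagged-pair graph.  When
    the genotype matrix is supplied, each flagged pair also carries its
    per-locus mismatch verification.  Pairs with undefined distance are
    excluded from flagging and reported separately.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ids = D.ids
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs: list[DuplicatePair] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dij = D.d[i, j]
            if math.isnan(dij) or not dij < threshold:
                continue
            pair = DuplicatePair(ids[i], ids[j], float(dij))
            if matrix is not None:
                cmp = verify_profiles(matrix, (ids[i], ids[j]))
                pair.mismatch_count = cmp.mismatch_count
                pair.mismatching_loci = cmp.mismatching_loci
            pairs.append(pair)
            parent[find(i)] = find(j)

    groups_map: dict[int, list[str]] = {}
    for k, name in enumerate(ids):
        groups_map.setdefault(find(k), []).append(name)
    groups = sorted(
        (sorted(g) for g in groups_map.values() if len(g) > 1), key=lambda g: g[0]
    )
    return DuplicateReport(threshold, pairs, groups, list(D.undefined_pairs))


# -- ROC ------------------------------------------------------------------


@dataclass
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RocCurve:
    points: list[RocPoint]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.points])


def threshold_roc(
    D: DissimilarityMatrix, clone_labels: Mapping[str, str]
) -> RocCurve:
    """Duplicate-calling ROC over all pairwise dissimilarities.

    Positives are pairs with the same clone label.  Thresholds sweep the
    observed d values (flagging d < t, matching the duplicate rule) plus
    one point above the maximum; AUC integrates sensitivity against
    1 - specificity by the trapezoid rule.  With a degenerate labelling
    (no negative pairs) specificity and AUC are NaN.
    """
    missing = [s for s in D.ids if s not in clone_labels]
    if missing:
        raise KeyError(f"clone_labels missing samples: {missing[:5]}")
    pos_d, neg_d = [], []
    for i in range(len(D.ids)):
        for j in range(i + 1, len(D.ids)):
            dij = D.d[i, j]
            if math.isnan(dij):
                continue
            same = clone_labels[D.ids[i]] == clone_labels[D.ids[j]]
            (pos_d if same else neg_d).append(dij)
    pos = np.asarray(pos_d)
    neg = np.asarray(neg_d)
    if pos.size == 0:
        raise ValueError("no positive (same-clone) pairs")
    observed = np.unique(np.concatenate([pos, neg]))
    thresholds = np.concatenate([[0.0], observed, [observed[-1] + 1e-9]])
    points = []
    for t in thresholds:
        sens = float((pos < t).mean())
        spec = float((neg >= t).mean()) if neg.size else math.nan
        points.append(RocPoint(float(t), sens, spec))
    if neg.size:
        fpr = np.array([1.0 - p.specificity for p in points])
        tpr = np.array([p.sensitivity for p in points])
        order = np.argsort(fpr, kind="stable")
        fpr, tpr = fpr[order], tpr[order]
        fpr = np.concatenate([[0.0], fpr, [1.0]])
        tpr = np.concatenate([[0.0], tpr, [1.0]])
        auc = float(np.trapezoid(tpr, fpr))
    else:
        auc = math.nan
    return RocCurve(points, auc)


def duplicate_precision_recall(
    report: DuplicateReport, clone_labels: Mapping[str, str], ids: Sequence[str]
) -> tuple[float, float]:
    """Precision/recall of flagged pairs against true clone labels."""
    flagged = {frozenset((p.sample_a, p.sample_b)) for p in report.pairs}
    truth = set()
    ids = list(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if clone_labels[ids[i]] == clone_labels[ids[j]]:
                truth.add(frozenset((ids[i], ids[j])))
    tp = len(flagged & truth)
    precision = tp / len(flagged) if flagged else math.nan
    recall = tp / len(truth) if truth else math.nan
    return precision, recall
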