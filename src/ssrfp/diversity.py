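"""Per-locus diversity and informativeness statistics.

Nei's gene diversity H = 1 - sum(p_i^2), with the finite-sample
correction H_c = n/(n-1) * H, and the polymorphism information content

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2,

are the field's standard summaries of how variable and how informative
a marker is.  ``summary_table`` assembles the per-locus report (allele
counts, size ranges, mean alleles per individual by sample group, H and
PIC under both frequency methods) plus unweighted aggregate means.

``n`` in the Nei correction is taken as the total number of observed
allele presences at the locus (summed over non-missing samples): with
dosage hidden, the distinct bands are the countable sampling units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, BinaryGenotypeMatrix
from .frequencies import AlleleFrequencySet


def _check_freqs(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < -1e-12):
        raise ValueError("p must be a non-negative 1-D frequency vector")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum():.6f}, expected 1")
    return np.clip(p, 0.0, None)


def nei_diversity(p: Sequence[float], n: int) -> tuple[float, float]:
    """(uncorrected, sample-size-corrected) Nei gene diversity.

    ``n`` is the number of sampled allele observations behind ``p``;
    the corrected value is n/(n-1) * (1 - sum p_i^2).
    """
    p = _check_freqs(p)
    if n < 2:
        raise ValueError("sample-size correction requires n >= 2")
    h = 1.0 - float(np.sum(p**2))
    return h, n / (n - 1) * h


def pic(p: Sequence[float]) -> float:
    """Polymorphism information content of a frequency vector."""
    p2 = _check_freqs(p) ** 2
    cross = (float(np.sum(p2)) ** 2 - float(np.sum(p2**2))) / 2.0
    return 1.0 - float(np.sum(p2)) - 2.0 * cross


def percent_change(uncorrected: float, corrected: float) -> float:
    """|corrected - uncorrected| / uncorrected * 100; NaN when undefined."""
    if uncorrected == 0:
        return math.nan
    return abs(corrected - uncorrected) / uncorrected * 100.0


def mean_alleles_per_individual(
    matrix: BinaryGenotypeMatrix, locus: str, group: str = "all"
) -> float:
    """Mean count of present alleles over non-missing samples of a group."""
    if group not in ("all", "study", "reference"):
        raise ValueError(f"unknown group {group!r}")
    block = matrix.locus_calls(locus)
    keep = np.ones(matrix.n_samples, dtype=bool)
    if group != "all":
        keep = np.array([s.group == group for s in matrix.samples])
    keep &= ~(block == MISSING).any(axis=1)
    if not keep.any():
        return math.nan
    return float((block[keep] == 1).sum(axis=1).mean())


def observed_allele_presences(matrix: BinaryGenotypeMatrix, locus: str) -> int:
    """Total present-allele count at a locus over non-missing samples."""
    block = matrix.locus_calls(locus)
    scored = ~(block == MISSING).any(axis=1)
    return int((block[scored] == 1).sum())


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson r; NaN when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y)[0])


@dataclass
class LocusDiversitySummary:
    locus: str
    n_alleles: int
    size_min_bp: int
    size_max_bp: int
    mean_alleles_total: float
    mean_alleles_reference: float
    mean_alleles_study: float
    n: int
    nei_uncorrected: float
    nei_corrected: float
    nei_pct_change: float
    pic_simple: float
    pic_em: float
    pic_pct_change: float


SUMMARY_COLUMNS = [
    "locus", "size_min_bp", "size_max_bp", "n_alleles",
    "mean_alleles_total", "mean_alleles_reference", "mean_alleles_study",
    "n", "nei_uncorrected", "nei_corrected", "nei_pct_change",
    "pic_simple", "pic_em", "pic_pct_change",
]


def summary_table(
    matrix: BinaryGenotypeMatrix,
    freq_simple: AlleleFrequencySet,
    freq_em: AlleleFrequencySet,
) -> list[LocusDiversitySummary]:
    """One diversity summary row per locus (marker-statistics report)."""
    rows = []
    for loc in matrix.loci:
        lf_s = freq_simple[loc.name]
        lf_e = freq_em[loc.name]
        n = observed_allele_presences(matrix, loc.name)
        if lf_s.undefined or n < 2:
            h_u = h_c = p_s = p_e = math.nan
        else:
            h_u, h_c = nei_diversity(lf_s.p, n)
            p_s = pic(lf_s.p)
            p_e = pic(lf_e.p)
        rows.append(
            LocusDiversitySummary(
                locus=loc.name,
                n_alleles=loc.n_alleles,
                size_min_bp=loc.allele_labels[0],
                size_max_bp=loc.allele_labels[-1],
                mean_alleles_total=mean_alleles_per_individual(matrix, loc.name),
                mean_alleles_reference=mean_alleles_per_individual(
                    matrix, loc.name, "reference"
                ),
                mean_alleles_study=mean_alleles_per_individual(
                    matrix, loc.name, "study"
                ),
                n=n,
                nei_uncorrected=h_u,
                nei_corrected=h_c,
                nei_pct_change=percent_change(h_u, h_c),
                pic_simple=p_s,
                pic_em=p_e,
                pic_pct_change=percent_change(p_s, p_e),
            )
        )
    return rows


def summary_frame(rows: list[LocusDiversitySummary]) -> pd.DataFrame:
    """Per-locus rows plus a trailing unweighted 'mean' aggregate row."""
    frame = pd.DataFrame([vars(r) for r in rows])[SUMMARY_COLUMNS]
    numeric = frame.drop(columns=["locus"]).mean(numeric_only=True)
    agg = {"locus": "mean", **{c: numeric.get(c, math.nan) for c in SUMMARY_COLUMNS[1:]}}
    return pd.concat([frame, pd.DataFrame([agg])], ignore_index=True)


# -- packaged published summaries -----------------------------------------


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_marker_summary() -> pd.DataFrame:
    """Published per-locus marker statistics for the 19-locus panel (65 samples)."""
    return pd.read_csv(_data_path("marker_summary.csv"))


def load_discrimination_summary() -> pd.DataFrame:
    """Published per-locus banding-pattern/discriminating-power table."""
    return pd.read_csv(_data_path("discrimination_summary.csv"))


def marker_summary_aggregates(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Aggregate statistics of a marker-summary table.

    Returns the total and mean allele counts, the unweighted means of
    corrected Nei diversity and of PIC under both frequency methods, and
    the Pearson correlations of the per-locus total mean allele number
    with corrected Nei diversity and with EM-corrected PIC.
    """
    t = load_marker_summary() if table is None else table
    return {
        "total_alleles": float(t["n_alleles"].sum()),
        "mean_alleles_per_locus": float(t["n_alleles"].mean()),
        "mean_nei_corrected": float(t["nei_corrected"].mean()),
        "mean_pic_simple": float(t["pic_simple"].mean()),
        "mean_pic_em": float(t["pic_em"].mean()),
        "r_mean_alleles_vs_nei": pearson_correlation(
            t["mean_alleles_total"], t["nei_corrected"]
        ),
        "r_mean_alleles_vs_pic": pearson_correlation(
            t["mean_alleles_total"], t["pic_em"]
        ),
    }
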