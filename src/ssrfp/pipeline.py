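"""End-to-end analysis pipeline producing the standard report bundle.

Stages: merge query into reference -> allele frequencies (uniform-split
and EM) -> diversity summary -> discrimination table + greedy panel
curve -> Jaccard dissimilarities -> NJ tree with locus bootstrap ->
duplicate report.  Everything is computed in memory first; files are
written only after every stage succeeds, so a failed run leaves no
partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

from . import clustering, discrimination, diversity, frequencies, io

log = logging.getLogger("ssrfp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    reference: str | Path
    query: str | Path | None = None
    ploidy: int = 6
    selfing_rate: float = 0.07
    duplicate_threshold: float = 0.05
    bootstrap_reps: int = 1000
    seed: int = 0
    outdir: str | Path = "ssrfp_out"
    merge_unshared_loci: str = "keep"
    clamp_negative_branches: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.duplicate_threshold < 1:
            raise ValueError("duplicate_threshold must be in (0, 1)")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


@dataclass
class ReportBundle:
    matrix: io.BinaryGenotypeMatrix
    freq_simple: frequencies.AlleleFrequencySet
    freq_em: frequencies.AlleleFrequencySet
    diversity_rows: list
    discrimination_table: object
    panel_curve: discrimination.PanelCurve
    distances: clustering.DissimilarityMatrix
    tree: object
    duplicates: clustering.DuplicateReport
    written_files: list[Path] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to ``outdir``."""

    def stage(name: str, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    dialect = {"ploidy": config.ploidy}
    reference = stage(
        "read_reference", lambda: io.read_genotype_table(config.reference, dialect)
    )
    if config.query is not None:
        query = stage(
            "read_query", lambda: io.read_genotype_table(config.query, dialect)
        )
        matrix = stage(
            "merge",
            lambda: io.merge_panels(reference, query, config.merge_unshared_loci),
        )
    else:
        matrix = reference

    fs = stage("simple_freq", lambda: frequencies.simple_freq(matrix))
    fe = stage(
        "em_freq",
        lambda: frequencies.em_freq(matrix, selfing_rate=config.selfing_rate),
    )
    rows = stage("diversity", lambda: diversity.summary_table(matrix, fs, fe))
    disc = stage("discrimination", lambda: discrimination.discrimination_table(matrix))
    curve = stage("greedy_panel", lambda: discrimination.greedy_panel(matrix))
    D = stage("jaccard", lambda: clustering.jaccard_matrix(matrix))
    if config.bootstrap_reps > 0:
        tree = stage(
            "tree",
            lambda: clustering.bootstrap_support(
                matrix,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
                clamp_negative=config.clamp_negative_branches,
            ),
        )
    else:
        tree = stage(
            "tree",
            lambda: clustering.nj_tree(D, config.clamp_negative_branches),
        )
    dup = stage(
        "duplicates",
        lambda: clustering.find_duplicates(
            D, config.duplicate_threshold, matrix=matrix
        ),
    )

    bundle = ReportBundle(matrix, fs, fe, rows, disc, curve, D, tree, dup)
    bundle.written_files = stage("write_outputs", lambda: _write(config, bundle))
    return bundle


def _write(config: PipelineConfig, b: ReportBundle) -> list[Path]:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def path(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    diversity.summary_frame(b.diversity_rows).to_csv(path("table2.csv"), index=False)
    b.discrimination_table.to_csv(path("table3.csv"), index=False)
    b.panel_curve.to_frame().to_csv(path("panel_curve.csv"), index=False)
    frequencies.write_frequency_table(b.freq_simple, b.freq_em, path("frequencies.csv"))
    b.distances.to_frame().to_csv(path("distances.csv"))
    b.distances.write_phylip(path("distances.phy"))
    path("tree.nwk").write_text(clustering.to_newick(b.tree) + "\n")
    b.duplicates.to_frame().to_csv(path("duplicates.csv"), index=False)
    path("duplicates.json").write_text(
        json.dumps(b.duplicates.to_json_payload(), indent=1)
    )
    try:
        pkg_version = _pkg_version("ssrfp")
    except Exception:  # editable/uninstalled checkout
        pkg_version = "unknown"
    run_log = {
        "package": "ssrfp",
        "version": pkg_version,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "n_samples": b.matrix.n_samples,
        "n_loci": len(b.matrix.loci),
        "n_flagged_pairs": len(b.duplicates.pairs),
        "n_duplicate_groups": len(b.duplicates.groups),
    }
    path("run_log.json").write_text(json.dumps(run_log, indent=1))
    return written
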