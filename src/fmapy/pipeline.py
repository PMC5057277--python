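"""End-to-end orchestration: alignments -> assignments -> abundances ->
comparison -> operon/pathway enrichment -> visualization exports.

Every stage is a pure function of its inputs and the configuration; rerunning
on identical inputs yields byte-identical data outputs (the run manifest
carries the only timestamp). A stage failure leaves previously completed
outputs in place alongside a ``.partial`` marker file naming the failed
stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from fmapy import __version__
from fmapy.alignment_filter import filter_file, write_assignments
from fmapy.compare import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_ABS_LOG2FC,
    DesignTable,
    run_comparison,
)
from fmapy.enrich import enrich_features, write_enrichment
from fmapy.quantify import (
    merge_samples,
    quantify_sample,
    write_sample_abundance,
    write_table,
)
from fmapy.refdb import load_reference
from fmapy.viz_export import heatmap_matrix, kegg_colors, write_heatmap, write_kegg_colors

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A named pipeline stage failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    protein_table: Path
    pathway_table: Path
    operon_table: Path
    design_table: Path
    alignment_files: dict[str, Path]  # sample_id -> .m8 path
    out_dir: Path
    evalue_max: float = 1e-3
    identity_min: float = 80.0
    method: str = "kruskal"
    filter_on: str = "raw"
    alpha: float = DEFAULT_ALPHA
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC
    universe_mode: str = "reference"
    heatmap_transform: str = "zscore_rows"

    def validate(self) -> None:
        paths = {
            "protein_table": self.protein_table,
            "pathway_table": self.pathway_table,
            "operon_table": self.operon_table,
            "design_table": self.design_table,
            **{f"alignment[{s}]": p for s, p in self.alignment_files.items()},
        }
        missing = [f"{k}: {v}" for k, v in paths.items() if not Path(v).exists()]
        if missing:
            raise FileNotFoundError("missing input file(s): " + "; ".join(missing))
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.evalue_max <= 0 or not (0 <= self.identity_min <= 100):
            raise ValueError("invalid filter thresholds")


def run_all(cfg: PipelineConfig) -> dict[str, object]:
    """Run the whole pipeline; returns the run manifest (also written as JSON).

    Artifacts, in stage order: per-sample assignment TSVs, per-sample
    abundance TSVs, merged raw and RPKM tables, comparison TSV, operon and
    pathway enrichment TSVs, KEGG color file, heatmap matrix TSV.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial = out / ".partial"
    manifest: dict[str, object] = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "thresholds": {
            "evalue_max": cfg.evalue_max,
            "identity_min": cfg.identity_min,
            "alpha": cfg.alpha,
            "min_abs_log2fc": cfg.min_abs_log2fc,
            "method": cfg.method,
            "filter_on": cfg.filter_on,
            "universe_mode": cfg.universe_mode,
        },
        "counts": {},
    }
    counts: dict[str, object] = manifest["counts"]  # type: ignore[assignment]

    stage = "load_reference"
    try:
        partial.write_text(stage + "\n")
        db = load_reference(cfg.protein_table, cfg.pathway_table, cfg.operon_table)
        design = DesignTable.from_tsv(cfg.design_table)
        counts["reference_kos"] = len(db.ko_universe)
        counts["reference_proteins"] = len(db.proteins)

        stage = "filter"
        partial.write_text(stage + "\n")
        per_sample = []
        assigned_per_sample: dict[str, int] = {}
        for sample_id, m8 in cfg.alignment_files.items():
            assignments = filter_file(
                m8, db, evalue_max=cfg.evalue_max, identity_min=cfg.identity_min
            )
            write_assignments(assignments, out / f"{sample_id}.assign.tsv")
            assigned_per_sample[sample_id] = len(assignments)
            per_sample.append(quantify_sample(sample_id, assignments))
        counts["reads_assigned"] = assigned_per_sample

        stage = "quantify"
        partial.write_text(stage + "\n")
        for sample in per_sample:
            write_sample_abundance(sample, out / f"{sample.sample_id}.abund.tsv")
        table = merge_samples(per_sample)
        write_table(table, out / "table.raw.tsv", metric="raw")
        write_table(table, out / "table.rpkm.tsv", metric="rpkm")
        counts["kos_quantified"] = len(table.kos)

        stage = "compare"
        partial.write_text(stage + "\n")
        comparison = run_comparison(
            table,
            design,
            method=cfg.method,
            filter_on=cfg.filter_on,
            alpha=cfg.alpha,
            min_abs_log2fc=cfg.min_abs_log2fc,
        )
        comparison.write_tsv(out / "comparison.tsv")
        counts["kos_tested"] = len(comparison.table)
        counts["da_kos"] = len(comparison.da_kos)

        detected = frozenset(table.kos)
        stage = "operon"
        partial.write_text(stage + "\n")
        operons = enrich_features(
            comparison, db, kind="operon",
            universe_mode=cfg.universe_mode, detected_kos=detected,
        )
        write_enrichment(operons, out / "operons.tsv")
        counts["da_operons"] = len(operons)

        stage = "pathway"
        partial.write_text(stage + "\n")
        pathways = enrich_features(
            comparison, db, kind="pathway",
            universe_mode=cfg.universe_mode, detected_kos=detected,
        )
        write_enrichment(pathways, out / "pathways.tsv")
        counts["pathways_tested"] = len(pathways)

        stage = "export"
        partial.write_text(stage + "\n")
        write_kegg_colors(kegg_colors(comparison), out / "kegg_colors.tsv")
        hm_kos = comparison.da_kos or frozenset(table.kos)
        write_heatmap(
            heatmap_matrix(table, ko_subset=hm_kos, transform=cfg.heatmap_transform),
            out / "heatmap.tsv",
        )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    partial.unlink(missing_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("run_all complete: %s", counts)
    return manifest
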