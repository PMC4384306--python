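"""End-to-end pipeline: inputs in, TSV/newick result bundle out.

``run_pipeline`` wires the whole analysis together: read the three inputs,
fit a :class:`~gapmer.model.GappedMatrixAnalysis`, and write per-pattern
weight matrices, threshold grids, TPR/FPR rate tables, ROC points with
AUROC, RZ tables, chi-square comparisons against the mononucleotide model,
prediction-vector correlation/distance matrices, a dendrogram, and a
machine-readable manifest.  All outputs are plain TSV (with '#' metadata
header lines) or newick; a fixed seed reproduces every number exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .io import iter_background_records, read_aligned_sites, read_peaks, write_tsv
from .model import GappedMatrixAnalysis, GappedMatrixResults
from .thresholds import ThresholdSpec

__all__ = ["RunConfig", "run_pipeline", "write_results"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    site_file: str
    peak_source: str
    background_source: str
    genome_file: str | None = None  # required when peak_source is BED
    output_dir: str = "gapmer_out"
    max_frame: int = 6
    pattern_selection: str | list = "all"
    center_length: int = 100
    n_scrambles: int = 100
    threshold: ThresholdSpec | None = None  # None: full sweep
    threshold_step: float = 0.25
    seed: int = 0
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.n_scrambles < 1:
            raise ValueError("n_scrambles must be >= 1")
        if self.center_length < 1:
            raise ValueError("center_length must be >= 1")


def run_pipeline(config: RunConfig) -> GappedMatrixResults:
    """Run the full analysis described by ``config`` and write all outputs."""
    model = GappedMatrixAnalysis(
        sites=read_aligned_sites(config.site_file),
        peaks=read_peaks(config.peak_source, config.genome_file),
        background=list(iter_background_records(config.background_source)),
        patterns=config.pattern_selection,
        max_frame=config.max_frame,
        center_length=config.center_length,
        n_scrambles=config.n_scrambles,
        seed=config.seed,
        both_strands=config.both_strands,
    )
    results = model.fit(threshold_step=config.threshold_step)
    write_results(results, config.output_dir, config)
    return results


def write_results(
    results: GappedMatrixResults, output_dir, config: RunConfig | None = None
) -> Path:
    """Write the TSV/newick result bundle and its manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = results.model
    meta = {
        "seed": model.seed,
        "n_peaks": len(model.peaks),
        "n_scrambles": model.n_scrambles,
        "center_length": model.center_length,
        "n_sites": model.sites.count,
        "site_length": model.sites.site_length,
    }
    manifest: dict = {"parameters": dict(meta), "files": {}}

    for name, entry in results.per_pattern.items():
        tag = f"id{entry['pattern'].type_id:02d}_{name}"
        wm_path = out / f"matrix_{tag}.tsv"
        entry["weight_matrix"].to_tsv(wm_path)
        manifest["files"].setdefault("matrices", []).append(wm_path.name)

        rate_path = out / f"rates_{tag}.tsv"
        xs = results.x_grid
        write_tsv(
            rate_path,
            {**meta, "pattern": name},
            ["x", "tau", "FPR", "TPR"],
            [
                (f"{x:g}", entry["tau_by_x"][x], fpr, tpr)
                for x, (fpr, tpr) in zip(xs, entry["rates"])
            ],
        )
        manifest["files"].setdefault("rates", []).append(rate_path.name)

    roc_path = out / "auroc.tsv"
    write_tsv(
        roc_path,
        meta,
        ["pattern", "AUROC"],
        [(k, f"{v:.10g}") for k, v in results.auroc.items()],
    )
    manifest["files"]["auroc"] = roc_path.name

    rz_path = out / "rz_scores.tsv"
    xs = results.x_grid
    write_tsv(
        rz_path,
        meta,
        ["pattern", "x", "tau", "RZ", "hits", "borderlines", "misses"],
        [
            (
                name,
                f"{x:g}",
                entry["tau_by_x"][x],
                res.rz,
                res.hits,
                res.borderlines,
                res.misses,
            )
            for name, entry in results.per_pattern.items()
            for x, res in ((x, entry["rz_by_x"][x]) for x in xs)
        ],
    )
    manifest["files"]["rz"] = rz_path.name

    if "m" in results.pattern_names and len(results.pattern_names) > 1:
        chi2_rows = []
        for x in xs:
            table = results.chi2_table(x, reference="m")
            for name, row in table.iterrows():
                chi2_rows.append(
                    (name, f"{x:g}", row["chi2"], row["df"], row["p_value"], row["band"])
                )
        chi2_path = out / "chi2_vs_m.tsv"
        write_tsv(
            chi2_path,
            meta,
            ["pattern", "x", "chi2", "df", "p_value", "band"],
            chi2_rows,
        )
        manifest["files"]["chi2"] = chi2_path.name

    if len(results.pattern_names) > 1:
        x0 = xs[0]
        corr = results.correlation_matrix(x0)
        corr_path = out / f"correlation_x{x0:g}.tsv"
        corr.to_csv(corr_path, sep="\t")
        manifest["files"]["correlation"] = corr_path.name
        newick = results.cluster(x0)
        tree_path = out / f"dendrogram_x{x0:g}.nwk"
        tree_path.write_text(newick + "\n")
        manifest["files"]["dendrogram"] = tree_path.name

    summary_path = out / "summary.tsv"
    results.summary().to_csv(summary_path, sep="\t")
    manifest["files"]["summary"] = summary_path.name

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("wrote %d result files to %s", sum(
        len(v) if isinstance(v, list) else 1 for v in manifest["files"].values()
    ), out)
    return out
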