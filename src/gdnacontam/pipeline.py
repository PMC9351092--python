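"""End-to-end workflow: regions -> profiles -> fit -> predict -> adjust -> DEG.

Consumes a directory in the layout ``simulate_experiment`` writes (annotation
GTF, chrom.sizes, design, FPKM matrix, per-library profiles) — real data
prepared in the same layout works identically — and emits a machine-readable
report plus per-stage tables.

The contamination FPKM subtracted from each library is computed from its
DNA-attributable intergenic fragments: the fitted unannotated-transcript
background (cDNA intercept term of the library's method) is removed from the
raw intergenic count first, playing the role that excluding assembled novel
transcripts from the intergenic region plays when alignments are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import contamination_model as cm
from . import deg_analysis as deg
from . import expression, io_utils
from .regions import (
    LibraryProfile,
    annotation_summary,
    build_intergenic_regions,
    merge_transcribed_regions,
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and the fixed analysis constants (all config-surfaced)."""

    input_dir: Path
    out_dir: Path | None = None
    fit_alpha: float = 0.05
    deg_alpha: float = 0.05
    correlation_alpha: float = 0.05
    offset: float = 0.01
    min_fpkm: float = 0.02
    low_fraction: float = 0.30
    lfc_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fit_alpha", "deg_alpha", "correlation_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("offset", "min_fpkm", "low_fraction", "lfc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def regression_points(
    profiles: Sequence[LibraryProfile], method: str
) -> tuple[list[float], list[float]]:
    """(DNA_a, mapping ratio) pairs of a method's known-concentration libraries."""
    pts = [
        (p.dna_a, p.mapping_ratio_ir)
        for p in profiles
        if p.method == method and p.dna_a is not None
    ]
    if not pts:
        raise ValueError(f"no libraries with known dna_a for method {method!r}")
    xs, ys = zip(*pts)
    return list(xs), list(ys)


def dna_fpkm_records(
    profiles: Sequence[LibraryProfile],
    estimate: cm.ContaminationEstimate,
    intergenic_length_kb: float,
) -> dict[str, expression.DnaFpkmRecord]:
    """Background-subtracted contamination FPKM per library."""
    records = {}
    for p in profiles:
        cdna = estimate.cdna_term_pa if p.method == "PA" else estimate.cdna_term_rz
        dna_fragments = max(p.mapping_ratio_ir - cdna, 0.0) * p.total_mapped
        records[p.library_id] = expression.fpkm_dna_for_library(
            library_id=p.library_id,
            intergenic_fragments=dna_fragments,
            total_reads_millions=p.total_mapped / 1e6,
            intergenic_length_kb=intergenic_length_kb,
        )
    return records


def _deg_block(
    matrix: expression.ExpressionMatrix,
    design: pd.DataFrame,
    method: str,
    config: PipelineConfig,
) -> dict:
    """Offset/filter one method's matrix, run every spike-vs-0 comparison and
    the gDNA correlation screen, and classify DEGs."""
    libs = design.index[design["method"] == method]
    sub = expression.ExpressionMatrix(
        values=matrix.values[list(libs)],
        adjusted=matrix.adjusted,
        n_clipped=matrix.n_clipped,
    )
    filtered, removed = deg.add_offset_and_filter(
        sub,
        offset=config.offset,
        min_fpkm=config.min_fpkm,
        max_low_fraction=config.low_fraction,
    )
    dna_a = design.loc[libs, "dna_a"]
    correlations = deg.correlate_with_gdna(
        filtered, dna_a, alpha=config.correlation_alpha
    )
    controls = list(dna_a.index[dna_a == 0.0])
    comparisons = {}
    for level in sorted(set(dna_a.dropna()) - {0.0}):
        treatment = list(dna_a.index[dna_a == level])
        if len(treatment) < 2 or len(controls) < 2:
            continue
        degs = deg.detect_degs(
            filtered,
            treatment,
            controls,
            alpha=config.deg_alpha,
            lfc_threshold=config.lfc_threshold,
        )
        classified, summary = deg.classify_degs(degs, correlations)
        comparisons[format(level, "g")] = {"summary": summary, "table": classified}
    return {
        "n_genes_removed": len(removed),
        "n_genes_tested": len(filtered.gene_ids),
        "n_correlated_genes": int(correlations["correlated"].sum()),
        "comparisons": comparisons,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) the report."""
    d = Path(config.input_dir)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineStageError(name, exc) from exc

    genes = stage("read_annotation", lambda: io_utils.read_gtf(d / "annotation.gtf"))
    chrom_sizes = stage(
        "read_annotation", lambda: io_utils.read_chrom_sizes(d / "chrom.sizes")
    )
    design = stage("read_design", lambda: io_utils.read_design(d / "design.tsv"))
    fpkm_values = stage(
        "read_expression", lambda: io_utils.read_matrix_tsv(d / "fpkm.tsv")
    )
    profiles = stage(
        "read_profiles", lambda: io_utils.read_profiles(d / "profiles.tsv")
    )

    def build_regions():
        transcribed = merge_transcribed_regions(genes, chrom_sizes=chrom_sizes)
        return build_intergenic_regions(chrom_sizes, transcribed)

    intergenic = stage("regions", build_regions)
    n_coding, n_noncoding = stage("regions", lambda: annotation_summary(genes))

    estimate = stage(
        "fit",
        lambda: cm.estimate_contamination(
            regression_points(profiles, "PA"),
            regression_points(profiles, "RZ"),
            n_coding,
            n_noncoding,
            alpha_level=config.fit_alpha,
        ),
    )

    def predict_all():
        rows = []
        for p in profiles:
            if p.method != "RZ":
                continue
            pred = cm.predict_gdna(
                p.mapping_ratio_ir, estimate.slope_rz, estimate.cdna_term_rz
            )
            rows.append(
                {
                    "library_id": p.library_id,
                    "dna_a": p.dna_a,
                    "mapping_ratio_IR": p.mapping_ratio_ir,
                    "gdna_predicted": pred.value,
                    "below_detection": pred.below_detection,
                }
            )
        return pd.DataFrame(rows).set_index("library_id")

    predictions = stage("predict", predict_all)

    matrix = expression.ExpressionMatrix(values=fpkm_values)
    records = stage(
        "adjust",
        lambda: dna_fpkm_records(profiles, estimate, intergenic.total_length_kb),
    )
    adjusted = stage("adjust", lambda: expression.adjust_matrix(matrix, records))

    deg_results = {}
    for method in sorted(design["method"].unique()):
        deg_results[method] = {
            "before": stage(
                f"deg_{method}", lambda m=method: _deg_block(matrix, design, m, config)
            ),
            "after": stage(
                f"deg_{method}",
                lambda m=method: _deg_block(adjusted, design, m, config),
            ),
        }

    report = {
        "fit": {
            m: {
                "slope": f.slope,
                "intercept": f.intercept,
                "slope_se": f.slope_se,
                "intercept_se": f.intercept_se,
                "r_squared": f.r_squared,
                "f_statistic": f.f_statistic,
                "f_df": list(f.f_df),
                "p_value": f.p_value,
                "n_points": f.n_points,
            }
            for m, f in (("PA", estimate.fit_pa), ("RZ", estimate.fit_rz))
        },
        "dna_r_hat": estimate.dna_r_hat,
        "dna_r_hat_percent": 100.0 * estimate.dna_r_hat,
        "cdna_term_pa": estimate.cdna_term_pa,
        "cdna_term_rz": estimate.cdna_term_rz,
        "coding_noncoding_ratio": estimate.coding_noncoding_ratio,
        "flags": {
            "pa_slope_significant": estimate.pa_slope_significant,
            "pa_intercept_clamped": estimate.pa_intercept_clamped,
            "dna_r_negative": estimate.dna_r_negative,
        },
        "n_coding": n_coding,
        "n_noncoding": n_noncoding,
        "intergenic_length_kb": intergenic.total_length_kb,
        "adjustment_clipped_cells": adjusted.n_clipped,
        "deg": {
            method: {
                phase: {
                    "n_genes_removed": block["n_genes_removed"],
                    "n_genes_tested": block["n_genes_tested"],
                    "n_correlated_genes": block["n_correlated_genes"],
                    "comparisons": {
                        lvl: comp["summary"]
                        for lvl, comp in block["comparisons"].items()
                    },
                }
                for phase, block in phases.items()
            }
            for method, phases in deg_results.items()
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_utils.write_json(report, out / "report.json")
        predictions.to_csv(out / "gdna_predictions.tsv", sep="\t")
        io_utils.write_matrix_tsv(adjusted.values, out / "fpkm_adjusted.tsv")
        for method, phases in deg_results.items():
            for phase, block in phases.items():
                for lvl, comp in block["comparisons"].items():
                    comp["table"].to_csv(
                        out / f"deg_{method}_{phase}_{lvl}.tsv", sep="\t", index=False
                    )
    return report
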