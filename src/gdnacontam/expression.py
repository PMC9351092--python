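"""FPKM computation and gDNA-contamination correction.

A gene's measured FPKM is the sum of its true RNA signal and a contamination
component.  Under the uniform-contamination assumption (gDNA fragments spread
evenly over the genome), the contamination FPKM is the same scalar for every
gene of a library and equals the FPKM of the intergenic region computed from
DNA-attributable intergenic fragments:

    FPKM_DNA = fragments_DNA_IR / (total_reads_millions * intergenic_len_kb)

Correction subtracts that scalar from every gene (FPKM_RNA = FPKM_total -
FPKM_DNA), clipping at zero.  Correction operates on raw FPKM, before the
+0.01 offset the DEG stage applies: subtracting a physical contamination
estimate from a pseudocounted value would bias small genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


class MatrixStateError(RuntimeError):
    """An operation was applied to a matrix in the wrong state."""


@dataclass
class ExpressionMatrix:
    """Genes x libraries FPKM values plus offset/adjustment state flags."""

    values: pd.DataFrame
    offset_applied: bool = False
    offset: float = 0.0
    adjusted: bool = False
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or library ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class DnaFpkmRecord:
    """The uniform per-gene contamination FPKM of one library."""

    library_id: str
    fpkm_dna: float
    intergenic_fragments: float
    total_reads_millions: float
    intergenic_length_kb: float

    def __post_init__(self) -> None:
        if self.fpkm_dna < 0:
            raise ValueError(f"{self.library_id}: fpkm_dna must be >= 0")


def compute_fpkm(
    counts: pd.DataFrame,
    lengths_kb: pd.Series,
    total_reads_millions: pd.Series,
) -> ExpressionMatrix:
    """FPKM = count / (total mapped reads in millions x gene length in kb)."""
    lengths_kb = lengths_kb.reindex(counts.index)
    if lengths_kb.isna().any():
        missing = list(lengths_kb.index[lengths_kb.isna()])[:5]
        raise KeyError(f"genes missing a length: {missing}")
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = total_reads_millions.reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])[:5]
        raise KeyError(f"libraries missing a total-read count: {missing}")
    if (totals <= 0).any():
        raise ValueError("total reads must be positive (undefined normalization)")
    values = counts.div(totals, axis=1).div(lengths_kb, axis=0)
    return ExpressionMatrix(values=values.astype(float))


def fpkm_dna_for_library(
    library_id: str,
    intergenic_fragments: float,
    total_reads_millions: float,
    intergenic_length_kb: float,
) -> DnaFpkmRecord:
    """Contamination FPKM of one library from its intergenic fragment count.

    The caller must ensure the intergenic region excludes assembled novel
    transcripts (otherwise unannotated-transcript fragments inflate the
    estimate); the pipeline achieves this by subtracting the fitted cDNA
    intercept term from the raw intergenic count first.
    """
    if intergenic_length_kb <= 0:
        raise ValueError("intergenic length must be positive")
    if total_reads_millions <= 0:
        raise ValueError("total reads must be positive")
    if intergenic_fragments < 0:
        raise ValueError("intergenic fragment count must be >= 0")
    return DnaFpkmRecord(
        library_id=library_id,
        fpkm_dna=intergenic_fragments / (total_reads_millions * intergenic_length_kb),
        intergenic_fragments=intergenic_fragments,
        total_reads_millions=total_reads_millions,
        intergenic_length_kb=intergenic_length_kb,
    )


def adjust_matrix(
    matrix: ExpressionMatrix,
    records: Iterable[DnaFpkmRecord] | Mapping[str, DnaFpkmRecord],
) -> ExpressionMatrix:
    """Subtract each library's contamination FPKM from every gene, clip at 0.

    Refuses matrices that are already adjusted or already offset (the
    correction is physical and must precede the DEG pseudocount).  The number
    of clipped cells is recorded on the result and logged.
    """
    if matrix.adjusted:
        raise MatrixStateError("matrix is already adjusted")
    if matrix.offset_applied:
        raise MatrixStateError("adjust before applying the DEG offset")
    if isinstance(records, Mapping):
        by_lib = {k: v.fpkm_dna for k, v in records.items()}
    else:
        by_lib = {r.library_id: r.fpkm_dna for r in records}
    unknown = set(by_lib) - set(matrix.library_ids)
    if unknown:
        raise KeyError(f"records for unknown libraries: {sorted(unknown)}")
    dna = pd.Series(by_lib, dtype=float).reindex(matrix.library_ids).fillna(0.0)
    shifted = matrix.values.sub(dna, axis=1)
    n_clipped = int((shifted < 0).to_numpy().sum())
    if n_clipped:
        logger.info("adjustment clipped %d negative cells to 0", n_clipped)
    return ExpressionMatrix(
        values=shifted.clip(lower=0.0),
        offset_applied=False,
        offset=0.0,
        adjusted=True,
        n_clipped=n_clipped,
    )
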