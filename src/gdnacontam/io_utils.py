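"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects: GTF is 1-based inclusive (converted to the package's 0-based
half-open coordinates on read); BED is 0-based half-open; matrices are TSV
with genes in rows and a header row of library ids; the design table carries
``library_id, method, dna_a, replicate`` with ``dna_a = "unknown"`` for
no-DNase libraries.  All round-trips are lossless for generated fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import CODING, NONCODING, GeneModel, LibraryProfile, RegionSet

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import SimulatedExperiment

GTF_SOURCE = "gdnacontam"
_BIOTYPE_OUT = {CODING: "protein_coding", NONCODING: "lncRNA"}
_BIOTYPE_IN = {
    "protein_coding": CODING,
    "coding": CODING,
    "noncoding": NONCODING,
    "lncRNA": NONCODING,
    "lincRNA": NONCODING,
    "miRNA": NONCODING,
    "snRNA": NONCODING,
    "snoRNA": NONCODING,
    "misc_RNA": NONCODING,
    "antisense": NONCODING,
    "processed_transcript": NONCODING,
}


class ParseError(ValueError):
    """A malformed line, reported with its line number."""

    def __init__(self, path: Path | str, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# GTF

def write_gtf(genes: Sequence[GeneModel], path: Path | str) -> None:
    """One ``gene`` feature line per gene, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            biotype = _BIOTYPE_OUT.get(g.biotype, g.biotype)
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{biotype}";'
            fh.write(
                f"{g.chrom}\t{GTF_SOURCE}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path: Path | str) -> list[GeneModel]:
    """Read gene-feature lines; non-gene features are skipped."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 fields, got {len(fields)}")
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from exc
            attrs = _parse_gtf_attributes(fields[8])
            if "gene_id" not in attrs:
                raise ParseError(path, lineno, "missing gene_id attribute")
            raw_biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            genes.append(
                GeneModel(
                    gene_id=attrs["gene_id"],
                    chrom=fields[0],
                    start=start - 1,  # GTF 1-based inclusive -> half-open
                    end=end,
                    strand=fields[6],
                    biotype=_BIOTYPE_IN.get(raw_biotype, raw_biotype),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# chrom.sizes / BED

def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: Path | str) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: Path | str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(path, lineno, "expected two columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad size: {exc}") from exc
    return sizes


def write_bed(
    intervals: RegionSet | Iterable[tuple[str, int, int]], path: Path | str
) -> None:
    it = intervals.iter_intervals() if isinstance(intervals, RegionSet) else intervals
    with open(path, "w") as fh:
        for chrom, start, end in it:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: Path | str) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 columns")
            try:
                out.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from exc
    return out


def read_fragments_sam(path: Path | str) -> list[tuple[str, int, int]]:
    """Alignment intervals of mapped primary records from a SAM file."""
    import pysam  # optional dependency, imported lazily

    fragments: list[tuple[str, int, int]] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            fragments.append(
                (rec.reference_name, rec.reference_start, rec.reference_end)
            )
    return fragments


# ---------------------------------------------------------------------------
# TSV tables

def write_matrix_tsv(values: pd.DataFrame, path: Path | str) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_design(design: pd.DataFrame, path: Path | str) -> None:
    out = design.copy()
    out["dna_a"] = out["dna_a"].map(
        lambda v: "unknown" if pd.isna(v) else format(v, "g")
    )
    out.to_csv(path, sep="\t", index_label="library_id")


def read_design(path: Path | str) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col="library_id")
    design["dna_a"] = pd.to_numeric(
        design["dna_a"].replace("unknown", np.nan), errors="raise"
    )
    return design


def write_profiles(profiles: Sequence[LibraryProfile], path: Path | str) -> None:
    rows = [
        {
            "library_id": p.library_id,
            "method": p.method,
            "dna_a": "unknown" if p.dna_a is None else format(p.dna_a, "g"),
            "total_mapped": repr(p.total_mapped),
            "intergenic_mapped": repr(p.intergenic_mapped),
            "mapping_ratio_IR": repr(p.mapping_ratio_ir),
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: Path | str) -> list[LibraryProfile]:
    table = pd.read_csv(path, sep="\t")
    profiles = []
    for _, row in table.iterrows():
        dna_a = None if str(row["dna_a"]) == "unknown" else float(row["dna_a"])
        profiles.append(
            LibraryProfile(
                library_id=str(row["library_id"]),
                method=str(row["method"]),
                dna_a=dna_a,
                total_mapped=float(row["total_mapped"]),
                intergenic_mapped=float(row["intergenic_mapped"]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# JSON reports

def write_json(obj: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# simulated-experiment bundle

def write_experiment(experiment: "SimulatedExperiment", out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gtf(experiment.annotation.genes, out_dir / "annotation.gtf")
    write_chrom_sizes(experiment.annotation.chrom_sizes, out_dir / "chrom.sizes")
    write_design(experiment.design, out_dir / "design.tsv")
    write_matrix_tsv(experiment.counts, out_dir / "counts.tsv")
    write_matrix_tsv(experiment.fpkm.values, out_dir / "fpkm.tsv")
    write_profiles(experiment.profiles, out_dir / "profiles.tsv")
    write_json(experiment.truth.scalar_dict(), out_dir / "truth.json")
    write_matrix_tsv(experiment.truth.rna_fpkm, out_dir / "truth_rna_fpkm.tsv")
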