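"""Synthetic spike-in dilution-series generator.

Emulates the study design the contamination model was calibrated on: total RNA
split into aliquots, genomic DNA spiked at mass fractions {0, 0.01%, 0.1%, 1%,
10%} on top of a residual post-DNase fraction ``DNA_r_true``, three replicates
per condition, sequenced with both a poly(A)-selection (PA) and an
rRNA-depletion (RZ) library preparation at fixed depth N.

Each library is a mixture of three fragment sources whose mass fractions sum
to one:

* gDNA, ``c_method * (DNA_a + DNA_r_true)``, spread uniformly over the genome
  (so its intergenic share is the realized intergenic fraction p_IR);
* an intergenic unannotated-transcript background, ``cDNA_IR_PA_true`` for PA
  and ``(1 + n_noncoding/n_coding) * cDNA_IR_PA_true`` for RZ;
* annotated cDNA, the remainder, distributed over captured genes (PA: coding
  only; RZ: coding + noncoding) proportionally to abundance x length.

By construction the expected intergenic mapping ratio is exactly linear in
DNA_a — the regression model holds with the scale coefficient alpha fixed at 1
(only products of alpha with the capture terms are identifiable).  Because
source fractions sum to one at fixed depth, contaminating fragments displace
RNA fragments: the annotated-cDNA share shrinks as DNA_a grows, and the truth
record stores the resulting per-library RNA-only FPKM (dilution included).

Counting noise is a single multinomial draw per library over (genes U
intergenic bin); ``noise="none"`` emits the exact expected counts as floats so
model identities hold to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import expression, io_utils
from .regions import (
    CODING,
    NONCODING,
    GeneModel,
    LibraryProfile,
    RegionSet,
    build_intergenic_regions,
    merge_transcribed_regions,
)

PA = "PA"
RZ = "RZ"
METHODS = (PA, RZ)
READ_LENGTH = 50  # bases; fragment placement detail only

# default Ribo-Zero cDNA intercept term and coding/noncoding scaling mirror the
# magnitudes of the fitted study model (slope ~0.657, cDNA term 0.035)
_DEFAULT_CDNA_IR_PA = 0.035 / 1.5


class SizingError(ValueError):
    """The genome cannot accommodate the requested genes."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic spike-in experiment.

    Defaults are the study conditions: a 50 Mb genome scaled down from the
    human case with ~73% intergenic space, residual gDNA 1.8% by mass,
    near-zero gDNA capture under poly(A) selection and 0.9 under rRNA
    depletion, and 2e6 fragments per library.
    """

    seed: int = 0
    genome_length: int = 50_000_000
    n_chromosomes: int = 5
    n_coding: int = 200
    n_noncoding: int = 100
    gene_length_range: tuple[int, int] = (20_000, 70_000)
    target_p_ir: float = 0.73
    expression_logmean: float = 0.0
    expression_logsd: float = 2.0
    dna_r_true: float = 0.018
    c_pa: float = 1e-6
    c_rz: float = 0.9
    cdna_ir_pa_true: float = _DEFAULT_CDNA_IR_PA
    spike_fractions: tuple[float, ...] = (0.0, 1e-4, 1e-3, 0.01, 0.10)
    replicates: int = 3
    fragments_per_library: int = 2_000_000
    noise: str = "multinomial"

    def __post_init__(self) -> None:
        if not 0 <= self.dna_r_true < 1:
            raise ValueError("dna_r_true must be in [0, 1)")
        if any(a < 0 for a in self.spike_fractions):
            raise ValueError("spike fractions must be >= 0")
        for name, c in (("c_pa", self.c_pa), ("c_rz", self.c_rz)):
            if not 0 < c <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.target_p_ir < 1:
            raise ValueError("target_p_ir must be in (0, 1)")
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("gene counts must be non-negative")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")
        if self.noise not in ("multinomial", "none"):
            raise ValueError("noise must be 'multinomial' or 'none'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cdna_ir_pa_true < 0:
            raise ValueError("cdna_ir_pa_true must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_coding + self.n_noncoding


@dataclass
class Annotation:
    """Generated annotation plus the fixed per-gene abundance profile theta."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    theta: np.ndarray  # per-gene expression abundance, aligned with genes
    transcribed: RegionSet
    realized_p_ir: float

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.length for g in self.genes], dtype=np.int64)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def intergenic(self) -> RegionSet:
        return build_intergenic_regions(self.chrom_sizes, self.transcribed)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every simulated dataset."""

    realized_p_ir: float
    dna_r_true: float
    c_pa: float
    c_rz: float
    cdna_ir_pa_true: float
    cdna_term_pa: float
    cdna_term_rz: float
    expected_mapping_ratio: dict[str, float]
    expected_dna_intergenic_fragments: dict[str, float]
    fpkm_dna_true: dict[str, float]
    rna_fpkm: pd.DataFrame  # genes x libraries, RNA-only FPKM

    def scalar_dict(self) -> dict:
        d = asdict(self)
        d.pop("rna_fpkm")
        return d


def _annotation_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    )


def library_rng(
    config: SimulationConfig, method_idx: int, fraction_idx: int, replicate: int
) -> np.random.Generator:
    """Independent substream per library; adding libraries never perturbs
    earlier ones."""
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(1, method_idx, fraction_idx, replicate)
        )
    )


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Place non-overlapping genes so the intergenic complement matches
    ``target_p_ir`` (drawn lengths are rescaled onto the genic budget, so the
    realized fraction lands within rounding of the target)."""
    rng = _annotation_rng(config)
    genome = config.genome_length
    n_chrom = config.n_chromosomes
    base = genome // n_chrom
    chrom_sizes = {f"chr{i + 1}": base for i in range(n_chrom)}
    chrom_sizes[f"chr{n_chrom}"] += genome - base * n_chrom

    n = config.n_genes
    if n == 0:
        return Annotation(
            genes=[],
            chrom_sizes=chrom_sizes,
            theta=np.empty(0),
            transcribed=RegionSet(),
            realized_p_ir=1.0,
        )

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n).astype(np.float64)
    budget = round((1.0 - config.target_p_ir) * genome)
    if budget < n:
        raise SizingError(
            f"genic budget {budget} bp cannot hold {n} genes of >= 1 bp"
        )
    lengths = np.maximum(1, np.rint(lengths * (budget / lengths.sum()))).astype(
        np.int64
    )

    biotypes = np.array([CODING] * config.n_coding + [NONCODING] * config.n_noncoding)
    rng.shuffle(biotypes)
    theta = rng.lognormal(config.expression_logmean, config.expression_logsd, size=n)

    # split genes over chromosomes proportionally to cumulative genic length
    chrom_names = list(chrom_sizes)
    chrom_cum = np.cumsum([chrom_sizes[c] for c in chrom_names]) / genome
    gene_cum = (np.cumsum(lengths) - lengths / 2) / lengths.sum()
    chrom_of = np.searchsorted(chrom_cum, gene_cum, side="left")
    chrom_of = np.minimum(chrom_of, n_chrom - 1)

    genes: list[GeneModel] = []
    theta_sorted: list[float] = []
    gid = 0
    for ci, cname in enumerate(chrom_names):
        idx = np.flatnonzero(chrom_of == ci)
        if not len(idx):
            continue
        clen = chrom_sizes[cname]
        total = int(lengths[idx].sum())
        if total > clen:
            raise SizingError(
                f"{cname}: {total} bp of genes exceed chromosome length {clen}"
            )
        k = len(idx)
        gaps = rng.multinomial(clen - total, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for j, gi in enumerate(idx):
            pos += int(gaps[j])
            start = pos
            end = start + int(lengths[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=cname,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=str(biotypes[gi]),
                )
            )
            theta_sorted.append(float(theta[gi]))
            pos = end
            gid += 1

    transcribed = merge_transcribed_regions(genes, chrom_sizes=chrom_sizes)
    realized_p_ir = 1.0 - int(lengths.sum()) / genome
    return Annotation(
        genes=genes,
        chrom_sizes=chrom_sizes,
        theta=np.array(theta_sorted),
        transcribed=transcribed,
        realized_p_ir=realized_p_ir,
    )


def expected_source_mix(
    config: SimulationConfig, method: str, dna_a: float
) -> dict[str, float]:
    """Per-source mass fractions {gdna, cdna_annotated, cdna_intergenic}.

    gDNA mass is ``c_method * (DNA_a + DNA_r_true)``; the intergenic
    unannotated-transcript background is the PA value, scaled by
    ``1 + n_noncoding/n_coding`` for RZ; annotated cDNA takes the remainder so
    the fractions sum to one.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if dna_a < 0:
        raise ValueError("dna_a must be >= 0")
    c = config.c_pa if method == PA else config.c_rz
    m_gdna = c * (dna_a + config.dna_r_true)
    if method == PA:
        m_intergenic = config.cdna_ir_pa_true
    else:
        if config.n_coding == 0 and config.cdna_ir_pa_true != 0:
            raise ZeroDivisionError(
                "RZ intergenic cDNA scaling needs n_coding > 0"
            )
        scale = 1.0 + (config.n_noncoding / config.n_coding if config.n_coding else 0.0)
        m_intergenic = scale * config.cdna_ir_pa_true
    m_rna = 1.0 - m_gdna - m_intergenic
    if m_rna <= 0:
        raise ValueError(
            f"contamination fractions ({m_gdna + m_intergenic:.3f}) leave no RNA mass"
        )
    return {
        "gdna": m_gdna,
        "cdna_annotated": m_rna,
        "cdna_intergenic": m_intergenic,
    }


def expected_mapping_ratio(
    config: SimulationConfig, method: str, dna_a: float, realized_p_ir: float
) -> float:
    """Model-implied intergenic mapping ratio: c*p_IR*(DNA_a+DNA_r) + cDNA term."""
    mix = expected_source_mix(config, method, dna_a)
    return mix["gdna"] * realized_p_ir + mix["cdna_intergenic"]


def _capture_mask(annotation: Annotation, method: str) -> np.ndarray:
    if method == PA:
        return np.array([g.biotype == CODING for g in annotation.genes])
    return np.ones(len(annotation.genes), dtype=bool)


def _source_probabilities(
    annotation: Annotation, config: SimulationConfig, method: str, dna_a: float
) -> tuple[np.ndarray, float]:
    """Per-gene and intergenic fragment probabilities; sums to 1 exactly in
    expectation (gene gDNA share uses gene length over genome, RNA share uses
    abundance x length over captured genes)."""
    mix = expected_source_mix(config, method, dna_a)
    lengths = annotation.lengths.astype(np.float64)
    genome = annotation.genome_length
    w = annotation.theta * lengths * _capture_mask(annotation, method)
    wsum = w.sum()
    if wsum == 0 and mix["cdna_annotated"] > 0:
        raise ValueError(f"no captured genes under {method} to carry RNA mass")
    w_hat = w / wsum if wsum > 0 else w
    p_gene = mix["gdna"] * lengths / genome + mix["cdna_annotated"] * w_hat
    p_intergenic = mix["gdna"] * annotation.realized_p_ir + mix["cdna_intergenic"]
    return p_gene, p_intergenic


def simulate_library(
    annotation: Annotation,
    method: str,
    dna_a: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    library_id: str | None = None,
    with_fragments: bool = False,
) -> tuple[LibraryProfile, np.ndarray, list[tuple[str, int, int]] | None]:
    """Allocate N fragments over (genes U intergenic bin).

    With multinomial noise the allocation is one multinomial draw; with
    ``noise="none"`` the counts are the exact expectations (floats).  Returns
    the library profile, per-gene counts aligned with ``annotation.genes``,
    and optionally a list of placed fragment intervals (0-based half-open).
    """
    n = config.fragments_per_library
    if n <= 0:
        raise ValueError("fragments_per_library must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_gene, p_intergenic = _source_probabilities(annotation, config, method, dna_a)
    if config.noise == "none":
        gene_counts = n * p_gene
        intergenic = n - float(gene_counts.sum())
        if -1e-6 * n < intergenic < 0:  # float residue when p_intergenic = 0
            intergenic = 0.0
    else:
        p = np.append(p_gene, p_intergenic)
        counts = rng.multinomial(n, p / p.sum())
        gene_counts = counts[:-1].astype(np.float64)
        intergenic = float(counts[-1])
    library_id = library_id or f"{method}_{dna_a:g}"
    profile = LibraryProfile(
        library_id=library_id,
        method=method,
        dna_a=dna_a,
        total_mapped=float(n),
        intergenic_mapped=intergenic,
    )
    fragments = (
        _place_fragments(annotation, gene_counts, intergenic, rng)
        if with_fragments
        else None
    )
    return profile, gene_counts, fragments


def _place_fragments(
    annotation: Annotation,
    gene_counts: np.ndarray,
    intergenic_count: float,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Uniform placement of fixed-length fragments within their source region."""
    fragments: list[tuple[str, int, int]] = []
    for gene, k in zip(annotation.genes, np.rint(gene_counts).astype(int)):
        if k <= 0:
            continue
        span = max(1, gene.length - READ_LENGTH + 1)
        starts = gene.start + rng.integers(0, span, size=k)
        flen = min(READ_LENGTH, gene.length)
        fragments.extend((gene.chrom, int(s), int(s) + flen) for s in starts)
    k = int(round(intergenic_count))
    if k > 0:
        ivs = list(annotation.intergenic().iter_intervals())
        if not ivs:
            raise ValueError("intergenic fragments requested but no intergenic space")
        lens = np.array([e - s for _, s, e in ivs], dtype=np.float64)
        picks = rng.choice(len(ivs), size=k, p=lens / lens.sum())
        for i in picks:
            chrom, s, e = ivs[i]
            span = max(1, (e - s) - READ_LENGTH + 1)
            start = s + int(rng.integers(0, span))
            fragments.append((chrom, start, start + min(READ_LENGTH, e - s)))
    return fragments


@dataclass
class SimulatedExperiment:
    """Full synthetic dataset: both methods x spike fractions x replicates."""

    config: SimulationConfig
    annotation: Annotation
    design: pd.DataFrame  # index library_id; columns method, dna_a, replicate
    counts: pd.DataFrame  # genes x libraries
    fpkm: "expression.ExpressionMatrix"
    profiles: list[LibraryProfile]
    truth: TruthRecord

    @property
    def library_ids(self) -> list[str]:
        return list(self.design.index)


def simulate_experiment(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    methods: Sequence[str] = METHODS,
) -> SimulatedExperiment:
    """Simulate the full dilution series and optionally write it to disk.

    Output files (all plain text): ``annotation.gtf``, ``chrom.sizes``,
    ``design.tsv``, ``counts.tsv``, ``fpkm.tsv``, ``profiles.tsv``,
    ``truth.json`` and ``truth_rna_fpkm.tsv``.
    """
    annotation = generate_annotation(config)
    lengths_kb = pd.Series(
        annotation.lengths / 1000.0, index=annotation.gene_ids, dtype=float
    )
    n = config.fragments_per_library
    total_m = n / 1e6

    rows = []
    count_cols: dict[str, np.ndarray] = {}
    profiles: list[LibraryProfile] = []
    exp_ratio: dict[str, float] = {}
    exp_dna_ir: dict[str, float] = {}
    fpkm_dna_true: dict[str, float] = {}
    rna_fpkm_cols: dict[str, np.ndarray] = {}
    genome = annotation.genome_length

    for mi, method in enumerate(METHODS):
        if method not in methods:
            continue
        for fi, dna_a in enumerate(config.spike_fractions):
            for rep in range(config.replicates):
                lib_id = f"{method}_{dna_a:g}_r{rep + 1}"
                rng = library_rng(config, mi, fi, rep)
                profile, gene_counts, _ = simulate_library(
                    annotation, method, dna_a, config, rng=rng, library_id=lib_id
                )
                profiles.append(profile)
                count_cols[lib_id] = gene_counts
                rows.append(
                    {
                        "library_id": lib_id,
                        "method": method,
                        "dna_a": dna_a,
                        "replicate": rep + 1,
                    }
                )
                mix = expected_source_mix(config, method, dna_a)
                exp_ratio[lib_id] = expected_mapping_ratio(
                    config, method, dna_a, annotation.realized_p_ir
                )
                exp_dna_ir[lib_id] = n * mix["gdna"] * annotation.realized_p_ir
                fpkm_dna_true[lib_id] = mix["gdna"] * 1e9 / genome
                w = (
                    annotation.theta
                    * annotation.lengths
                    * _capture_mask(annotation, method)
                )
                w_hat = w / w.sum() if w.sum() > 0 else w
                with np.errstate(divide="ignore", invalid="ignore"):
                    rna_fpkm_cols[lib_id] = (
                        mix["cdna_annotated"] * w_hat * 1e9 / annotation.lengths
                    )

    design = pd.DataFrame(rows).set_index("library_id")
    counts = pd.DataFrame(count_cols, index=annotation.gene_ids)
    fpkm = expression.compute_fpkm(
        counts,
        lengths_kb,
        pd.Series(total_m, index=counts.columns, dtype=float),
    )
    truth = TruthRecord(
        realized_p_ir=annotation.realized_p_ir,
        dna_r_true=config.dna_r_true,
        c_pa=config.c_pa,
        c_rz=config.c_rz,
        cdna_ir_pa_true=config.cdna_ir_pa_true,
        cdna_term_pa=config.cdna_ir_pa_true,
        cdna_term_rz=(
            (1.0 + config.n_noncoding / config.n_coding) * config.cdna_ir_pa_true
            if config.n_coding
            else config.cdna_ir_pa_true
        ),
        expected_mapping_ratio=exp_ratio,
        expected_dna_intergenic_fragments=exp_dna_ir,
        fpkm_dna_true=fpkm_dna_true,
        rna_fpkm=pd.DataFrame(rna_fpkm_cols, index=annotation.gene_ids),
    )
    experiment = SimulatedExperiment(
        config=config,
        annotation=annotation,
        design=design,
        counts=counts,
        fpkm=fpkm,
        profiles=profiles,
        truth=truth,
    )
    if out_dir is not None:
        io_utils.write_experiment(experiment, Path(out_dir))
    return experiment
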