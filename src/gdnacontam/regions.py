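"""Genome interval arithmetic for the intergenic mapping ratio.

The intergenic region is the strand-ignored complement of everything
transcribed (annotated gene bodies plus any assembled novel-transcript
intervals).  Fragments overlapping it by at least one base are attributed to
genomic-DNA contamination plus an unannotated-transcript background; the
fraction of a library's mapped fragments that land there is the intergenic
mapping ratio, the response variable of the spike-in regression.

All coordinates are 0-based half-open internally.  GTF I/O converts to and
from the 1-based inclusive dialect (see :mod:`gdnacontam.io_utils`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CODING = "coding"
NONCODING = "noncoding"


class CoordinateError(ValueError):
    """An interval falls outside its declared chromosome."""


class BiotypeError(ValueError):
    """A gene carries a biotype outside {coding, noncoding}."""


class UndefinedRatioError(ZeroDivisionError):
    """A ratio was requested with a zero denominator."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: an interval with a biotype.

    ``length_kb`` is the unit that enters FPKM arithmetic; biotype membership
    (coding vs noncoding) drives the coding/noncoding gene-count ratio used to
    scale the unannotated-transcript intercept term between library-prep
    methods.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = CODING

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length / 1000.0


@dataclass(frozen=True)
class LibraryProfile:
    """Per-library fragment summary feeding the regression.

    ``dna_a`` is the nominal spiked gDNA mass fraction (0.10 for "10%"), or
    ``None`` for libraries whose gDNA content is unknown (no-DNase libraries);
    those are excluded from fitting and only scored by prediction.  Counts may
    be non-integral for noise-free simulated libraries (exact expectations).
    """

    library_id: str
    method: str  # "PA" or "RZ"
    dna_a: float | None
    total_mapped: float
    intergenic_mapped: float

    def __post_init__(self) -> None:
        if not (0 <= self.intergenic_mapped <= self.total_mapped):
            raise ValueError(
                f"{self.library_id}: intergenic count {self.intergenic_mapped} "
                f"outside [0, {self.total_mapped}]"
            )

    @property
    def mapping_ratio_ir(self) -> float:
        return compute_mapping_ratio(self.intergenic_mapped, self.total_mapped)


class RegionSet:
    """Per-chromosome sorted, disjoint, merged intervals (0-based half-open)."""

    def __init__(self, intervals: Mapping[str, np.ndarray] | None = None):
        # invariant: arrays are (n, 2) int64, sorted, merged (non-adjacent)
        self._ivs: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if len(arr):
                    self._ivs[chrom] = _merge_sorted(arr[np.argsort(arr[:, 0])])

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end <= start:
                raise CoordinateError(f"invalid interval {chrom}:[{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()})

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._ivs)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.empty((0, 2), dtype=np.int64))

    def iter_intervals(self) -> Iterable[tuple[str, int, int]]:
        for chrom in self.chromosomes:
            for start, end in self._ivs[chrom]:
                yield chrom, int(start), int(end)

    @property
    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._ivs.values())
        )

    @property
    def total_length_kb(self) -> float:
        return self.total_length / 1000.0

    def __len__(self) -> int:
        return sum(len(arr) for arr in self._ivs.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return list(self.iter_intervals()) == list(other.iter_intervals())

    def __repr__(self) -> str:
        return (
            f"RegionSet({len(self)} intervals on {len(self._ivs)} chromosomes, "
            f"{self.total_length} bp)"
        )


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge intervals already sorted by start; adjacent intervals coalesce."""
    if len(arr) <= 1:
        return arr.copy()
    out = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return np.array(out, dtype=np.int64)


def merge_transcribed_regions(
    genes: Sequence[GeneModel],
    novel_transcripts: Iterable[tuple[str, int, int]] = (),
    chrom_sizes: Mapping[str, int] | None = None,
) -> RegionSet:
    """Union of gene bodies and novel-transcript intervals, strand-ignored.

    If *chrom_sizes* is given, intervals beyond a chromosome end raise
    :class:`CoordinateError`.
    """
    intervals = [(g.chrom, g.start, g.end) for g in genes]
    intervals.extend((c, int(s), int(e)) for c, s, e in novel_transcripts)
    if chrom_sizes is not None:
        for chrom, start, end in intervals:
            if chrom not in chrom_sizes:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise CoordinateError(
                    f"interval {chrom}:[{start}, {end}) beyond chromosome end "
                    f"{chrom_sizes[chrom]}"
                )
    return RegionSet.from_intervals(intervals)


def build_intergenic_regions(
    chrom_sizes: Mapping[str, int], transcribed: RegionSet
) -> RegionSet:
    """Exact per-chromosome complement of *transcribed* within the genome."""
    out: dict[str, np.ndarray] = {}
    for chrom in transcribed.chromosomes:
        if chrom not in chrom_sizes:
            raise KeyError(f"chromosome {chrom!r} absent from chrom_sizes")
    for chrom, size in chrom_sizes.items():
        ivs = transcribed.intervals(chrom)
        if len(ivs) and ivs[-1, 1] > size:
            raise CoordinateError(
                f"transcribed region on {chrom} exceeds chromosome length {size}"
            )
        # complement of a sorted merged set: gaps between consecutive intervals
        bounds = np.concatenate([[0], ivs.ravel(), [size]])
        gaps = bounds.reshape(-1, 2)
        gaps = gaps[gaps[:, 1] > gaps[:, 0]]
        if len(gaps):
            out[chrom] = gaps
    return RegionSet(out)


def count_fragments_in_regions(
    fragments: Iterable[tuple[str, int, int]],
    regions: RegionSet,
    mode: str = "overlap",
) -> int:
    """Number of fragments hitting *regions*.

    ``mode="overlap"`` (default) counts a fragment when it shares >= 1 base
    with any region; ``mode="contained"`` requires the fragment to lie fully
    inside a single region.  Fragments on chromosomes absent from *regions*
    count as non-overlapping (logged once).
    """
    if mode not in ("overlap", "contained"):
        raise ValueError(f"unknown counting mode {mode!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    unknown: set[str] = set()
    for chrom, start, end in fragments:
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for chrom, frags in by_chrom.items():
        ivs = regions.intervals(chrom)
        if not len(ivs):
            if chrom not in regions.chromosomes:
                unknown.add(chrom)
            continue
        arr = np.asarray(frags, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        region_starts, region_ends = ivs[:, 0], ivs[:, 1]
        if mode == "overlap":
            # rightmost region starting before the fragment end; since regions
            # are disjoint+sorted, its end is the max end among candidates
            idx = np.searchsorted(region_starts, ends, side="left")
            hit = (idx > 0) & (region_ends[np.maximum(idx - 1, 0)] > starts)
        else:
            idx = np.searchsorted(region_starts, starts, side="right")
            hit = (idx > 0) & (region_ends[np.maximum(idx - 1, 0)] >= ends)
        total += int(hit.sum())
    if unknown:
        logger.warning(
            "fragments on %d chromosome(s) absent from regions counted as "
            "non-overlapping: %s", len(unknown), sorted(unknown)
        )
    return total


def compute_mapping_ratio(intergenic_mapped: float, total_mapped: float) -> float:
    """Intergenic mapping ratio: intergenic fragments / total mapped fragments."""
    if total_mapped <= 0:
        raise UndefinedRatioError("total_mapped must be positive")
    ratio = intergenic_mapped / total_mapped
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"mapping ratio {ratio} outside [0, 1]")
    return ratio


def annotation_summary(genes: Sequence[GeneModel]) -> tuple[int, int]:
    """Exact (n_coding, n_noncoding) counts by biotype."""
    bad = sorted({g.biotype for g in genes if g.biotype not in (CODING, NONCODING)})
    if bad:
        raise BiotypeError(f"unknown biotype(s): {bad}")
    n_coding = sum(1 for g in genes if g.biotype == CODING)
    return n_coding, len(genes) - n_coding
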