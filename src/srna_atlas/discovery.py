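"""Transcript calling from pooled coverage.

The caller operationalizes a coverage-threshold discovery procedure for
bacterial intergenic small RNAs:

1. find maximal runs of bases whose pooled depth exceeds a cutoff
   (default 100 reads/nt), per strand;
2. join adjacent runs separated by short sub-threshold gaps (default
   <= 5 nt);
3. drop short regions (default < 50 nt);
4. keep only regions residing *entirely* within intergenic space —
   a region overlapping any annotated gene, on either strand and by even
   a single base, is discarded rather than trimmed;
5. classify each surviving region as an independent sRNA or as a UTR of
   the adjacent gene, using the gap to the nearest same-strand gene and
   the similarity of expression at that gene's end.

Step 5 replaces manual curation by visual inspection with an explicit,
parameterized rule: a region is a UTR iff it has (almost) no gap to a
same-strand gene, or it is close (<= 50 nt) and its expression is similar
(within a configurable fold) to the adjacent gene end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .coverage import CoverageTrack
from .errors import DataError
from .quantify import CountMatrix

SRNA = "sRNA"
UTR = "UTR"


class Region(NamedTuple):
    """A raw called region, 1-based inclusive, single strand."""

    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneLike(NamedTuple):
    """Minimal view of an annotated gene used by the caller."""

    id: str
    start: int
    end: int
    strand: str


@dataclass
class CallerParams:
    """Tunable parameters of the transcript caller.

    cutoff:
        Depth threshold in reads/nt; bases with depth strictly greater
        than this seed a region.
    max_join_gap:
        Adjacent regions separated by a sub-threshold gap of at most this
        many nt are merged.
    min_length:
        Regions shorter than this are dropped.
    utr_max_gap:
        A region at most this far from a same-strand gene is a UTR
        outright (the "no gap" clause).
    utr_expression_ratio:
        For regions within ``utr_proximity`` of a same-strand gene, the
        region is a UTR when the mean depth over the 20 nt of the
        adjacent gene end is at least the region's mean depth divided by
        this ratio (the "similar expression" clause).
    utr_proximity:
        Maximum gap for the similar-expression clause.
    sum_strands:
        Call on strand-summed depth instead of per strand.
    """

    cutoff: float = 100.0
    max_join_gap: int = 5
    min_length: int = 50
    utr_max_gap: int = 10
    utr_expression_ratio: float = 2.0
    utr_proximity: int = 50
    gene_end_window: int = 20
    sum_strands: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise DataError("cutoff must be > 0")
        if self.max_join_gap < 0:
            raise DataError("max_join_gap must be >= 0")
        if self.min_length < 1:
            raise DataError("min_length must be >= 1")
        if self.utr_expression_ratio < 1:
            raise DataError("utr_expression_ratio must be >= 1")


@dataclass
class TranscriptCall:
    """A called transcript with provenance attributes.

    Coordinates are 1-based inclusive; ``length = end - start + 1``.
    ``flank_gap_upstream``/``flank_gap_downstream`` are the distances in
    nt to the nearest annotated gene on the genomic left/right (any
    strand); ``None`` when no gene exists on that side.
    """

    id: str
    start: int
    end: int
    strand: str
    klass: str
    max_depth: int
    mean_depth: float
    flank_gap_upstream: int | None = None
    flank_gap_downstream: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    starts = edges[0::2] + 1  # 1-based
    ends = edges[1::2]  # 1-based inclusive
    return list(zip(starts.tolist(), ends.tolist()))


def call_regions(track: CoverageTrack, cutoff: float, sum_strands: bool = False) -> list[Region]:
    """Maximal runs of consecutive bases with depth strictly above ``cutoff``.

    Regions are returned per strand (or on strand-summed depth with
    ``sum_strands``, reported as strand ``+``), ordered by start within
    each strand.
    """
    if cutoff <= 0:
        raise DataError("cutoff must be > 0")
    regions: list[Region] = []
    if sum_strands:
        for s, e in _runs(track.summed() > cutoff):
            regions.append(Region(s, e, "+"))
        return regions
    for strand in ("+", "-"):
        for s, e in _runs(track.depth(strand) > cutoff):
            regions.append(Region(s, e, strand))
    return regions


def join_gaps(regions: Sequence[Region], max_join_gap: int) -> list[Region]:
    """Merge same-strand regions separated by gaps of at most ``max_join_gap`` nt.

    Input must be sorted by start within each strand.  A single
    left-to-right pass reaches the fixed point, so the operation is
    idempotent.
    """
    out: list[Region] = []
    by_strand: dict[str, list[Region]] = {}
    for r in regions:
        by_strand.setdefault(r.strand, []).append(r)
    for strand, regs in by_strand.items():
        starts = [r.start for r in regs]
        if starts != sorted(starts):
            raise DataError(f"regions on strand {strand} are not sorted by start")
        merged: list[Region] = []
        for r in regs:
            if merged and r.start - merged[-1].end - 1 <= max_join_gap:
                merged[-1] = Region(merged[-1].start, max(merged[-1].end, r.end), strand)
            else:
                merged.append(r)
        out.extend(merged)
    out.sort(key=lambda r: (r.strand, r.start))
    return out


def filter_length(regions: Iterable[Region], min_length: int) -> list[Region]:
    """Keep regions whose length is at least ``min_length`` nt."""
    return [r for r in regions if r.length >= min_length]


def intersect_intergenic(regions: Iterable[Region], genes: Sequence[GeneLike]) -> list[Region]:
    """Keep regions residing entirely within intergenic space.

    A region is retained iff it overlaps no gene on *either* strand;
    any partial overlap discards the whole region (no trimming).
    """
    out = []
    for r in regions:
        if not any(g.start <= r.end and r.start <= g.end for g in genes):
            out.append(r)
    return out


def _nearest_same_strand_gene(region: Region, genes: Sequence[GeneLike]) -> tuple[GeneLike | None, int]:
    """Nearest gene on the region's strand and the gap to it (nt, >= 0)."""
    best: GeneLike | None = None
    best_gap = -1
    for g in genes:
        if g.strand != region.strand:
            continue
        if g.end < region.start:
            gap = region.start - g.end - 1
        elif g.start > region.end:
            gap = g.start - region.end - 1
        else:  # overlapping gene: gap 0 (cannot happen for intergenic regions)
            gap = 0
        if best is None or gap < best_gap:
            best, best_gap = g, gap
    return best, best_gap


def classify_utr(
    region: Region,
    track: CoverageTrack,
    genes: Sequence[GeneLike],
    params: CallerParams | None = None,
) -> str:
    """Classify an intergenic region as ``"sRNA"`` or ``"UTR"``.

    UTR iff the gap to the nearest same-strand gene is at most
    ``utr_max_gap`` nt, or the gap is at most ``utr_proximity`` nt and the
    mean depth over the ``gene_end_window`` nt of that gene's
    region-facing end is at least the region's mean depth divided by
    ``utr_expression_ratio``.
    """
    params = params or CallerParams()
    gene, gap = _nearest_same_strand_gene(region, genes)
    if gene is None:
        return SRNA
    if gap <= params.utr_max_gap:
        return UTR
    if gap <= params.utr_proximity:
        w = params.gene_end_window
        if gene.end < region.start:  # gene to the left: its right end faces the region
            lo, hi = max(gene.start, gene.end - w + 1), gene.end
        else:  # gene to the right
            lo, hi = gene.start, min(gene.end, gene.start + w - 1)
        gene_end_depth = float(np.mean(track.slice_depth(lo, hi, region.strand)))
        region_depth = float(np.mean(track.slice_depth(region.start, region.end, region.strand)))
        if gene_end_depth >= region_depth / params.utr_expression_ratio:
            return UTR
    return SRNA


def _flank_gaps(region: Region, genes: Sequence[GeneLike]) -> tuple[int | None, int | None]:
    left = [region.start - g.end - 1 for g in genes if g.end < region.start]
    right = [g.start - region.end - 1 for g in genes if g.start > region.end]
    return (min(left) if left else None, min(right) if right else None)


@dataclass
class CallResult:
    """Called transcripts plus the per-stage filtering funnel."""

    calls: list[TranscriptCall]
    funnel: dict[str, int] = field(default_factory=dict)

    @property
    def srnas(self) -> list[TranscriptCall]:
        return [c for c in self.calls if c.klass == SRNA]

    @property
    def utrs(self) -> list[TranscriptCall]:
        return [c for c in self.calls if c.klass == UTR]


def call_transcripts(
    track: CoverageTrack,
    genes: Sequence[GeneLike],
    params: CallerParams | None = None,
    id_prefix: str = "SR",
) -> CallResult:
    """Run the full caller: threshold, join, length-filter, intergenic, classify.

    Calls are numbered by genomic coordinate (``SR001`` ...).  The funnel
    records how many regions survive each stage, mirroring the narrative
    of a discovery pipeline's filtering steps.
    """
    params = params or CallerParams()
    raw = call_regions(track, params.cutoff, sum_strands=params.sum_strands)
    joined = join_gaps(raw, params.max_join_gap)
    long_enough = filter_length(joined, params.min_length)
    intergenic = intersect_intergenic(long_enough, genes)
    intergenic = sorted(intergenic, key=lambda r: (r.start, r.end, r.strand))
    calls: list[TranscriptCall] = []
    width = max(3, len(str(len(intergenic))))
    for i, region in enumerate(intergenic, start=1):
        depth = track.slice_depth(region.start, region.end, region.strand)
        klass = classify_utr(region, track, genes, params)
        up, down = _flank_gaps(region, genes)
        calls.append(
            TranscriptCall(
                id=f"{id_prefix}{i:0{width}d}",
                start=region.start,
                end=region.end,
                strand=region.strand,
                klass=klass,
                max_depth=int(depth.max()),
                mean_depth=float(depth.mean()),
                flank_gap_upstream=up,
                flank_gap_downstream=down,
            )
        )
    funnel = {
        "raw_regions": len(raw),
        "after_join": len(joined),
        "after_length_filter": len(long_enough),
        "intergenic": len(intergenic),
        "srna": sum(c.klass == SRNA for c in calls),
        "utr": sum(c.klass == UTR for c in calls),
    }
    return CallResult(calls, funnel)


def transcript_length(start: int, end: int) -> int:
    """Length of a transcript under the 1-based inclusive convention."""
    if start > end:
        raise DataError(f"start {start} > end {end}")
    return end - start + 1


def detection_status(counts: CountMatrix, threshold: float = 1.0) -> "np.ndarray":
    """Detected/undetected flag per feature from cumulative MEV.

    A feature is detected iff its cumulative MEV (all-sample reads divided
    by length) is at least ``threshold`` (default 1 read/nt); a feature at
    exactly the threshold counts as detected.  Returns a boolean pandas
    Series indexed by feature.
    """
    cumulative = counts.counts.sum(axis=1) / counts.lengths
    return cumulative >= threshold
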