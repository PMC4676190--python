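"""Per-base, per-strand read coverage tracks.

A :class:`CoverageTrack` holds stranded read depth over a (bacterial-sized)
genome as two integer arrays.  Depth at a base is the number of supplied read
intervals spanning it — every base a read covers contributes, which is the
convention needed when coverage profiles are later used to delimit transcript
boundaries.  Tracks from individual libraries can be pooled by element-wise
summation, mirroring the common practice of merging all libraries before
transcript discovery to maximise depth.

Coordinates are 1-based inclusive throughout the package; conversion to the
0-based half-open conventions of BED/bedGraph happens only in :mod:`.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

STRANDS = ("+", "-")


@dataclass
class CoverageTrack:
    """Stranded per-base read depth.

    Attributes
    ----------
    genome_length:
        Number of bases; both strand arrays have exactly this length.
    forward, reverse:
        Integer read depth for the ``+`` and ``-`` strands; index ``i``
        holds the depth at 1-based position ``i + 1``.
    sample_ids:
        Identifiers of the libraries that contributed to this track.
    """

    genome_length: int
    forward: np.ndarray
    reverse: np.ndarray
    sample_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.int64)
        self.reverse = np.asarray(self.reverse, dtype=np.int64)
        if len(self.forward) != self.genome_length or len(self.reverse) != self.genome_length:
            raise DataError(
                f"strand arrays must have length {self.genome_length}, got "
                f"{len(self.forward)} (+) and {len(self.reverse)} (-)"
            )
        if (self.forward < 0).any() or (self.reverse < 0).any():
            raise DataError("coverage depths must be non-negative")
        self.sample_ids = tuple(self.sample_ids)

    @classmethod
    def zeros(cls, genome_length: int, sample_ids: Sequence[str] = ()) -> "CoverageTrack":
        return cls(
            genome_length,
            np.zeros(genome_length, dtype=np.int64),
            np.zeros(genome_length, dtype=np.int64),
            tuple(sample_ids),
        )

    def depth(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.forward
        if strand == "-":
            return self.reverse
        raise DataError(f"unknown strand {strand!r}")

    def slice_depth(self, start: int, end: int, strand: str) -> np.ndarray:
        """Depth over the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.genome_length):
            raise DataError(f"interval [{start}, {end}] outside genome of length {self.genome_length}")
        return self.depth(strand)[start - 1 : end]

    def total(self) -> int:
        """Sum of depth over all bases and both strands (= sum of read lengths)."""
        return int(self.forward.sum() + self.reverse.sum())

    def summed(self) -> np.ndarray:
        """Strand-summed depth, for strand-agnostic calling."""
        return self.forward + self.reverse


def pileup(
    reads: pd.DataFrame,
    genome_length: int,
    sample_ids: Sequence[str] | None = None,
) -> CoverageTrack:
    """Build a coverage track from read intervals.

    ``reads`` needs columns ``start``, ``end`` (1-based inclusive) and
    ``strand``; an optional ``sample`` column is used to derive
    ``sample_ids`` when none are given.  Depth at base ``p`` equals the
    number of intervals covering ``p`` on that strand.

    Raises
    ------
    DataError
        If any interval lies outside ``[1, genome_length]`` or has
        ``end < start``; the error names the offending record.
    """
    if genome_length < 1:
        raise DataError("genome_length must be >= 1")
    track = CoverageTrack.zeros(genome_length)
    if len(reads) == 0:
        track.sample_ids = tuple(sample_ids or ())
        return track

    starts = reads["start"].to_numpy(dtype=np.int64)
    ends = reads["end"].to_numpy(dtype=np.int64)
    strands = reads["strand"].to_numpy()

    bad = (starts < 1) | (ends > genome_length) | (ends < starts)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        rec = reads.iloc[i]
        raise DataError(
            f"read interval out of bounds at row {reads.index[i]}: "
            f"[{rec['start']}, {rec['end']}] ({rec['strand']}) on genome of length {genome_length}"
        )
    unknown = ~np.isin(strands, STRANDS)
    if unknown.any():
        i = int(np.flatnonzero(unknown)[0])
        raise DataError(f"unknown strand {strands[i]!r} at row {reads.index[i]}")

    for strand, arr in (("+", track.forward), ("-", track.reverse)):
        sel = strands == strand
        if not sel.any():
            continue
        diff = np.zeros(genome_length + 1, dtype=np.int64)
        np.add.at(diff, starts[sel] - 1, 1)
        np.add.at(diff, ends[sel], -1)
        arr += np.cumsum(diff)[:genome_length]

    if sample_ids is None and "sample" in reads.columns:
        sample_ids = tuple(pd.unique(reads["sample"]))
    track.sample_ids = tuple(sample_ids or ())
    return track


def pool(tracks: Iterable[CoverageTrack]) -> CoverageTrack:
    """Element-wise sum of coverage tracks (library merging).

    All tracks must share ``genome_length``; ``sample_ids`` are
    concatenated in order.  Total depth of the pooled track equals the sum
    of the member totals exactly (integer arithmetic).
    """
    tracks = list(tracks)
    if not tracks:
        raise DataError("cannot pool an empty list of tracks")
    length = tracks[0].genome_length
    for t in tracks[1:]:
        if t.genome_length != length:
            raise DataError(f"genome length mismatch: {t.genome_length} != {length}")
    fwd = np.sum([t.forward for t in tracks], axis=0)
    rev = np.sum([t.reverse for t in tracks], axis=0)
    ids: list[str] = []
    for t in tracks:
        ids.extend(t.sample_ids)
    return CoverageTrack(length, fwd, rev, tuple(ids))
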