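"""Readers and writers for the text formats the pipeline speaks.

Internal coordinates are 1-based inclusive everywhere; BED and bedGraph
are written and read in their native 0-based half-open convention, with
the conversion happening exactly once at this boundary (a bedGraph record
``chrom 99 149 12`` corresponds to internal bases [100, 149] at depth
12).  GFF3 is 1-based inclusive natively and round-trips unchanged.

Malformed lines raise :class:`~srna_atlas.errors.FormatError` carrying
the file path and line number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .discovery import GeneLike, TranscriptCall
from .errors import DataError, FormatError

DEFAULT_SEQID = "genome"
_SOURCE = "srna-atlas"


# ---------------------------------------------------------------------------
# GFF3

@dataclass
class GffRecord:
    """One GFF3 feature line (1-based inclusive coordinates)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = _SOURCE
    score: str = "."

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")


def _escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _unescape(value: str) -> str:
    return value.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")


def write_gff3(records: Iterable[GffRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = ";".join(f"{k}={_escape(str(v))}" for k, v in rec.attributes.items())
            fh.write(
                f"{rec.seqid}\t{rec.source}\t{rec.type}\t{rec.start}\t{rec.end}\t"
                f"{rec.score}\t{rec.strand}\t.\t{attrs or '.'}\n"
            )


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Parse a GFF3 file; malformed lines raise FormatError with line number."""
    path = Path(path)
    records: list[GffRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            seqid, source, ftype, start_s, end_s, score, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}",
                    path=str(path), line=lineno,
                ) from None
            if start < 1 or end < start:
                raise FormatError(
                    f"invalid interval [{start}, {end}]", path=str(path), line=lineno
                )
            if strand not in ("+", "-", "."):
                raise FormatError(f"invalid strand {strand!r}", path=str(path), line=lineno)
            attributes: dict[str, str] = {}
            if attr_s not in (".", ""):
                for item in attr_s.split(";"):
                    if not item:
                        continue
                    if "=" not in item:
                        raise FormatError(
                            f"malformed attribute {item!r}", path=str(path), line=lineno
                        )
                    k, v = item.split("=", 1)
                    attributes[k] = _unescape(v)
            records.append(
                GffRecord(seqid, ftype, start, end, strand, attributes, source, score)
            )
    return records


def annotation_to_records(
    genes: Sequence, planted: Sequence = (), seqid: str = DEFAULT_SEQID
) -> list[GffRecord]:
    """GFF3 records for genes and (optionally) planted truth with class attribute."""
    records = [
        GffRecord(seqid, "gene", g.start, g.end, g.strand, {"ID": g.id})
        for g in genes
    ]
    for p in planted:
        attrs = {"ID": p.id, "class": p.klass, "base_mean": f"{p.base_mean:.6g}"}
        if getattr(p, "host_gene", None):
            attrs["host_gene"] = p.host_gene
        records.append(GffRecord(seqid, "transcript", p.start, p.end, p.strand, attrs))
    return records


def calls_to_records(calls: Sequence[TranscriptCall], seqid: str = DEFAULT_SEQID) -> list[GffRecord]:
    records = []
    for c in calls:
        attrs = {
            "ID": c.id,
            "class": c.klass,
            "max_depth": str(c.max_depth),
            "mean_depth": f"{c.mean_depth:.4f}",
        }
        if c.flank_gap_upstream is not None:
            attrs["flank_gap_upstream"] = str(c.flank_gap_upstream)
        if c.flank_gap_downstream is not None:
            attrs["flank_gap_downstream"] = str(c.flank_gap_downstream)
        records.append(GffRecord(seqid, "transcript", c.start, c.end, c.strand, attrs))
    return records


def records_to_genes(records: Iterable[GffRecord], types: tuple[str, ...] = ("gene",)) -> list[GeneLike]:
    """Extract gene intervals (for the intergenic filter) from GFF3 records."""
    genes = []
    for i, rec in enumerate(records):
        if rec.type not in types:
            continue
        gid = rec.id or f"{rec.type}_{i + 1}"
        if rec.strand not in ("+", "-"):
            raise DataError(f"gene {gid} has no strand")
        genes.append(GeneLike(gid, rec.start, rec.end, rec.strand))
    return genes


# ---------------------------------------------------------------------------
# BED6 read intervals

def write_bed(reads: pd.DataFrame, path: str | Path, chrom: str = DEFAULT_SEQID) -> None:
    """Write read intervals as BED6 (0-based half-open); name = sample id."""
    path = Path(path)
    with path.open("w") as fh:
        for row in reads.itertuples(index=False):
            fh.write(
                f"{chrom}\t{row.start - 1}\t{row.end}\t{getattr(row, 'sample', '.')}\t0\t{row.strand}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 intervals into the internal 1-based inclusive frame."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"expected >= 6 BED fields, got {len(fields)}", path=str(path), line=lineno
                )
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("non-integer BED coordinates", path=str(path), line=lineno) from None
            if start0 < 0 or end0 <= start0:
                raise FormatError(
                    f"invalid BED interval [{start0}, {end0})", path=str(path), line=lineno
                )
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FormatError(f"invalid strand {strand!r}", path=str(path), line=lineno)
            rows.append((start0 + 1, end0, strand, fields[3]))
    return pd.DataFrame(rows, columns=["start", "end", "strand", "sample"])


# ---------------------------------------------------------------------------
# bedGraph coverage

def _strand_path(prefix: str | Path, strand: str) -> Path:
    tag = "plus" if strand == "+" else "minus"
    return Path(f"{prefix}.{tag}.bedgraph")


def write_bedgraph(track: CoverageTrack, prefix: str | Path, chrom: str = DEFAULT_SEQID) -> list[Path]:
    """Write one bedGraph per strand (``<prefix>.plus/.minus.bedgraph``).

    Runs of equal non-zero depth become one 0-based half-open record.
    """
    paths = []
    for strand in ("+", "-"):
        depth = track.depth(strand)
        path = _strand_path(prefix, strand)
        with path.open("w") as fh:
            boundaries = np.flatnonzero(np.diff(depth)) + 1
            edges = np.concatenate(([0], boundaries, [len(depth)]))
            for lo, hi in zip(edges[:-1], edges[1:]):
                value = int(depth[lo])
                if value != 0:
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{value}\n")
        paths.append(path)
    return paths


def _read_bedgraph_file(path: Path, genome_length: int) -> np.ndarray:
    depth = np.zeros(genome_length, dtype=np.int64)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"expected 4 bedGraph fields, got {len(fields)}", path=str(path), line=lineno
                )
            try:
                start0, end0, value = int(fields[1]), int(fields[2]), int(float(fields[3]))
            except ValueError:
                raise FormatError("non-numeric bedGraph fields", path=str(path), line=lineno) from None
            if start0 < 0 or end0 <= start0 or end0 > genome_length:
                raise FormatError(
                    f"bedGraph interval [{start0}, {end0}) outside genome of length {genome_length}",
                    path=str(path), line=lineno,
                )
            depth[start0:end0] = value
    return depth


def read_bedgraph(prefix: str | Path, genome_length: int, sample_ids: Sequence[str] = ()) -> CoverageTrack:
    """Read a per-strand bedGraph pair written by :func:`write_bedgraph`."""
    fwd = _read_bedgraph_file(_strand_path(prefix, "+"), genome_length)
    rev = _read_bedgraph_file(_strand_path(prefix, "-"), genome_length)
    return CoverageTrack(genome_length, fwd, rev, tuple(sample_ids))


# ---------------------------------------------------------------------------
# TSV tables

def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    if "sample" not in df.columns or "condition" not in df.columns:
        raise FormatError("sample sheet needs 'sample' and 'condition' columns", path=str(path))
    return df.set_index("sample")


def write_counts(cm, path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.rename_axis("feature").reset_index().to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, samples: pd.DataFrame):
    from .quantify import CountMatrix

    df = pd.read_csv(path, sep="\t").set_index("feature")
    if "length" not in df.columns:
        raise FormatError("counts table needs a 'length' column", path=str(path))
    lengths = df.pop("length")
    return CountMatrix(df, lengths, samples)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.rename_axis(index_label).reset_index().to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, index_col: str = "feature") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index(index_col)


def calls_to_frame(calls: Sequence[TranscriptCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": c.id,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "strand": c.strand,
                "class": c.klass,
                "max_depth": c.max_depth,
                "mean_depth": c.mean_depth,
                "flank_gap_upstream": c.flank_gap_upstream,
                "flank_gap_downstream": c.flank_gap_downstream,
            }
            for c in calls
        ]
    ).set_index("feature")
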