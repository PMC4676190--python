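"""Read counting per transcript and mean expression values (MEV).

The MEV of a feature is its read count divided by its length in
nucleotides (reads/nt).  The *cumulative* MEV uses reads from every
library; *condition-specific* MEVs use only the libraries of one
condition.  Both are computed on raw (unnormalized) counts, matching the
raw-read definition of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .discovery import TranscriptCall


@dataclass
class CountMatrix:
    """Integer read counts for features across samples.

    Attributes
    ----------
    counts:
        ``features x samples`` DataFrame of non-negative integers.
    lengths:
        Feature length in nt (>= 1), indexed like ``counts``.
    samples:
        Sample sheet indexed by sample id with at least a ``condition``
        column and optionally ``replicate``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()
            raise DataError(f"missing lengths for features {missing[:5]}")
        if (self.lengths < 1).any():
            raise DataError("feature lengths must be >= 1 nt")
        if "condition" not in self.samples.columns:
            raise DataError("sample sheet must have a 'condition' column")
        extra = [s for s in self.counts.columns if s not in self.samples.index]
        if extra:
            raise DataError(f"samples missing from sample sheet: {extra}")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        if len(sel) == 0:
            raise DataError(f"no samples for condition {condition!r}")
        return list(sel)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)].copy(),
            self.lengths.copy(),
            self.samples.loc[list(sample_ids)].copy(),
        )


def count_reads(
    reads: pd.DataFrame,
    calls: Sequence["TranscriptCall"],
    samples: pd.DataFrame,
) -> CountMatrix:
    """Assign reads to called transcripts and tally per-sample counts.

    A read is counted for a call iff it overlaps the call by >= 1 nt on
    the same strand.  A read overlapping several calls is assigned to the
    one with the largest overlap; ties go to the leftmost (smallest start)
    call.  Reads overlapping no call are dropped.

    ``reads`` needs columns ``start``, ``end``, ``strand``, ``sample``.
    ``samples`` is the sample sheet (indexed by sample id, with a
    ``condition`` column); samples with zero assigned reads keep a zero
    column.
    """
    ids = [c.id for c in calls]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate call ids")
    lengths = pd.Series({c.id: c.end - c.start + 1 for c in calls}, dtype=np.int64)
    counts = pd.DataFrame(
        np.zeros((len(calls), len(samples.index)), dtype=np.int64),
        index=pd.Index(ids, name="feature"),
        columns=samples.index,
    )
    if len(reads) and len(calls):
        # order call columns by (start, end) so argmax resolves ties leftmost
        order = sorted(range(len(calls)), key=lambda i: (calls[i].start, calls[i].end))
        for strand in ("+", "-"):
            sub = [i for i in order if calls[i].strand == strand]
            rsel = reads[reads["strand"] == strand]
            if not sub or rsel.empty:
                continue
            cs = np.array([calls[i].start for i in sub])
            ce = np.array([calls[i].end for i in sub])
            rs = rsel["start"].to_numpy()[:, None]
            re = rsel["end"].to_numpy()[:, None]
            ov = np.minimum(re, ce[None, :]) - np.maximum(rs, cs[None, :]) + 1
            np.clip(ov, 0, None, out=ov)
            best = np.argmax(ov, axis=1)  # first max -> leftmost call
            hit = ov[np.arange(len(rsel)), best] > 0
            assigned = pd.DataFrame(
                {
                    "feature": [calls[sub[b]].id for b in best[hit]],
                    "sample": rsel["sample"].to_numpy()[hit],
                }
            )
            tab = assigned.groupby(["feature", "sample"]).size()
            for (feat, samp), n in tab.items():
                if samp not in counts.columns:
                    raise DataError(f"read sample {samp!r} not in sample sheet")
                counts.loc[feat, samp] += int(n)
    return CountMatrix(counts, lengths, samples.copy())


def mev(total_reads: float, length: int) -> float:
    """Mean expression value: read count divided by feature length (reads/nt)."""
    if length < 1:
        raise DataError("length must be >= 1")
    return float(total_reads) / float(length)


def mev_table(cm: CountMatrix) -> pd.DataFrame:
    """Cumulative and condition-specific MEVs for every feature.

    Returns a DataFrame with a ``cumulative`` column (all-sample reads /
    length) and one column per condition (that condition's reads /
    length), all in reads/nt on raw counts.
    """
    out = pd.DataFrame(index=cm.features)
    out["cumulative"] = cm.counts.sum(axis=1) / cm.lengths
    for cond in cm.conditions:
        out[cond] = cm.counts[cm.samples_for(cond)].sum(axis=1) / cm.lengths
    return out


MEV_BIN_LABELS = ("<1", "1-10", "10-100", ">100")


def mev_bins(values: Sequence[float] | np.ndarray) -> pd.Series:
    """Histogram of MEVs over the bins <1, [1,10), [10,100) and >=100.

    The partition is exhaustive, so the counts sum to ``len(values)``.
    """
    v = np.asarray(list(values), dtype=float)
    if (v < 0).any():
        raise DataError("MEVs must be non-negative")
    edges = np.array([1.0, 10.0, 100.0])
    idx = np.searchsorted(edges, v, side="right")
    counts = np.bincount(idx, minlength=4)
    return pd.Series(counts, index=list(MEV_BIN_LABELS), dtype=np.int64)


def length_bins(lengths: Sequence[int], bin_width: int = 25, max_edge: int = 400) -> pd.Series:
    """Histogram of transcript lengths in fixed-width bins with an overflow bin.

    Bins are ``[0, w), [w, 2w), ..., [max_edge - w, max_edge), [max_edge, inf)``.
    """
    if bin_width < 1 or max_edge % bin_width:
        raise DataError("max_edge must be a positive multiple of bin_width")
    v = np.asarray(list(lengths), dtype=float)
    if (v < 0).any():
        raise DataError("lengths must be non-negative")
    edges = np.arange(bin_width, max_edge + bin_width, bin_width, dtype=float)
    idx = np.searchsorted(edges, v, side="right")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    labels = [f"{int(lo)}-{int(lo) + bin_width}" for lo in np.arange(0, max_edge, bin_width)]
    labels.append(f">={max_edge}")
    return pd.Series(counts, index=labels, dtype=np.int64)
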