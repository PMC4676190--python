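"""Synthetic genomes, planted transcripts, counts and coverage.

Everything downstream of this module — the caller, the counting layer,
normalization, testing and the comparative analytics — can be exercised
against a known ground truth produced here.  The generator emulates the
salient features of a bacterial small-RNA sequencing experiment:

* a single circular chromosome carrying non-overlapping protein-coding
  genes on both strands, separated by intergenic gaps (placement ignores
  circularity: no feature spans the origin);
* planted intergenic sRNAs, 50-300 nt by default, kept clear of the
  flanking genes, and planted UTR-like transcripts abutting a gene end
  (gap 0) on the same strand;
* per-sample read counts drawn from a negative binomial with mean
  ``base_mean x length x fold_change(condition) x library_size_factor``
  and dispersion ``phi`` (variance ``mu + phi mu^2``; ``phi = 0``
  degenerates to Poisson);
* read intervals laid down uniformly *within* each feature and a low
  Poisson background over intergenic space, so that thresholded coverage
  recovers the planted features while exercising the cutoff's specificity.

All randomness flows through a single integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, pileup
from .discovery import GeneLike
from .errors import DataError, PlacementError
from .quantify import CountMatrix

DEFAULT_GENOME_LENGTH = 50_000
DEFAULT_N_GENES = 20
DEFAULT_N_SRNA = 15
DEFAULT_N_UTR = 5
DEFAULT_CONDITIONS = ("control", "stress")
DEFAULT_REPLICATES = 3
DEFAULT_DISPERSION = 0.1
DEFAULT_READ_LENGTH = 50
DEFAULT_NOISE_DEPTH = 1.0
DEFAULT_GENE_BASE_MEAN = 0.5
DEFAULT_BASE_MEAN_RANGE = (2.0, 6.0)
MIN_PLANTED_LENGTH = 30
MAX_PLANTED_LENGTH = 400


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def as_gene_like(self) -> GeneLike:
        return GeneLike(self.id, self.start, self.end, self.strand)


@dataclass(frozen=True)
class PlantedTranscript:
    """A planted feature with its expression program.

    ``base_mean`` is the expected read count per nucleotide per sample at
    fold change 1 and library factor 1; ``fold_changes`` maps condition
    names to multiplicative fold changes (conditions absent from the map
    have fold 1).
    """

    id: str
    start: int
    end: int
    strand: str
    klass: str  # "sRNA" | "UTR"
    base_mean: float
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    host_gene: str | None = None  # the abutted gene, for UTRs

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def fold(self, condition: str) -> float:
        return float(self.fold_changes.get(condition, 1.0))


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated experiment."""

    genome_length: int
    genes: list[Gene] = field(default_factory=list)
    planted: list[PlantedTranscript] = field(default_factory=list)
    dispersion: float = DEFAULT_DISPERSION
    seed: int = 0
    gene_base_mean: float = DEFAULT_GENE_BASE_MEAN

    def gene_likes(self) -> list[GeneLike]:
        return [g.as_gene_like() for g in self.genes]

    def srnas(self) -> list[PlantedTranscript]:
        return [p for p in self.planted if p.klass == "sRNA"]

    def utrs(self) -> list[PlantedTranscript]:
        return [p for p in self.planted if p.klass == "UTR"]

    def validate(self) -> None:
        """Check the structural invariants of the planted truth.

        Raises :class:`DataError` on the first violation: overlapping
        genes, an sRNA not fully intergenic or closer than 20 nt to a
        gene, a UTR whose gap to its host gene is not 0, a planted length
        outside [30, 400] nt, or a non-positive fold change.
        """
        if self.dispersion < 0:
            raise DataError("dispersion must be >= 0")
        genes = sorted(self.genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            if b.start <= a.end:
                raise DataError(f"genes {a.id} and {b.id} overlap")
        for p in self.planted:
            if not (1 <= p.start <= p.end <= self.genome_length):
                raise DataError(f"planted {p.id} outside genome")
            if not (MIN_PLANTED_LENGTH <= p.length <= MAX_PLANTED_LENGTH):
                raise DataError(f"planted {p.id} length {p.length} outside [30, 400]")
            if any(f <= 0 for f in p.fold_changes.values()):
                raise DataError(f"planted {p.id} has a non-positive fold change")
            overlaps = [g for g in self.genes if g.start <= p.end and p.start <= g.end]
            if p.klass == "sRNA":
                if overlaps:
                    raise DataError(f"sRNA {p.id} overlaps gene {overlaps[0].id}")
                gaps = [
                    p.start - g.end - 1 if g.end < p.start else g.start - p.end - 1
                    for g in self.genes
                ]
                if gaps and min(gaps) < 20:
                    raise DataError(f"sRNA {p.id} has < 20 nt clearance to a gene")
            elif p.klass == "UTR":
                if overlaps:
                    raise DataError(f"UTR {p.id} overlaps gene {overlaps[0].id}")
                host = next((g for g in self.genes if g.id == p.host_gene), None)
                if host is None:
                    raise DataError(f"UTR {p.id} has no host gene")
                gap = p.start - host.end - 1 if host.end < p.start else host.start - p.end - 1
                if gap != 0 or host.strand != p.strand:
                    raise DataError(f"UTR {p.id} does not abut gene {host.id} on the same strand")
            else:
                raise DataError(f"planted {p.id} has unknown class {p.klass!r}")


def generate_annotation(
    genome_length: int = DEFAULT_GENOME_LENGTH,
    n_genes: int = DEFAULT_N_GENES,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (400, 1200),
    gap_range: tuple[int, int] = (300, 900),
    max_retries: int = 50,
) -> SyntheticTruth:
    """Place non-overlapping genes separated by intergenic gaps.

    Genes are laid left to right with gap and length drawn uniformly from
    the given ranges, so every adjacent pair is separated by at least
    ``gap_range[0]`` nt (>= 200 by default).  Deterministic given the
    seed; raises :class:`PlacementError` when the genes cannot fit after
    ``max_retries`` fresh draws.
    """
    if n_genes < 1:
        raise DataError("n_genes must be >= 1")
    if genome_length < 1:
        raise DataError("genome_length must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        cursor = 0  # end of previous feature (0 = origin)
        genes: list[Gene] = []
        ok = True
        for i in range(n_genes):
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            start = cursor + gap + 1
            end = start + length - 1
            if end > genome_length - gap_range[0]:
                ok = False
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"gene{i + 1:03d}", start, end, strand))
            cursor = end
        if ok:
            return SyntheticTruth(genome_length=genome_length, genes=genes, seed=seed)
    raise PlacementError(
        f"could not place {n_genes} genes of {gene_length_range} nt with gaps "
        f"{gap_range} on a genome of {genome_length} nt"
    )


def _gaps(truth: SyntheticTruth) -> list[tuple[int, int]]:
    """Intergenic intervals (1-based inclusive), including chromosome ends."""
    genes = sorted(truth.genes, key=lambda g: g.start)
    gaps = []
    prev_end = 0
    for g in genes:
        if g.start - 1 > prev_end:
            gaps.append((prev_end + 1, g.start - 1))
        prev_end = g.end
    if prev_end < truth.genome_length:
        gaps.append((prev_end + 1, truth.genome_length))
    return gaps


def plant_transcripts(
    truth: SyntheticTruth,
    n_srna: int = DEFAULT_N_SRNA,
    n_utr: int = DEFAULT_N_UTR,
    length_range: tuple[int, int] = (50, 300),
    seed: int = 0,
    clearance: int = 20,
    min_separation: int = 25,
    base_mean_range: tuple[float, float] = DEFAULT_BASE_MEAN_RANGE,
) -> SyntheticTruth:
    """Plant intergenic sRNAs and gene-abutting UTRs into the truth.

    sRNAs are placed fully inside intergenic gaps with at least
    ``clearance`` nt to both flanking genes and ``min_separation`` nt to
    every other planted feature.  UTRs abut the downstream end of a
    randomly chosen gene (gap 0, same strand) and extend into the
    intergenic gap, also respecting ``min_separation``.  Expression
    levels (``base_mean``, reads/nt/sample) are drawn uniformly from
    ``base_mean_range``; fold changes start at 1 everywhere (see
    :func:`assign_fold_changes`).

    Returns a new truth; the input is not mutated.  Raises
    :class:`PlacementError` when there is not enough intergenic space.
    """
    if not (MIN_PLANTED_LENGTH <= length_range[0] <= length_range[1] <= MAX_PLANTED_LENGTH):
        raise DataError(f"length_range must lie within [{MIN_PLANTED_LENGTH}, {MAX_PLANTED_LENGTH}]")
    rng = np.random.default_rng(seed)
    new = dataclasses.replace(truth, planted=list(truth.planted))
    occupied: list[tuple[int, int]] = [(p.start, p.end) for p in new.planted]
    genes_sorted = sorted(new.genes, key=lambda g: g.start)

    def free(start: int, end: int) -> bool:
        return all(end < s - min_separation or start > e + min_separation for s, e in occupied)

    # --- UTRs: abut the 3' (downstream) end of a gene, same strand
    if n_utr > len(genes_sorted):
        raise PlacementError(f"cannot plant {n_utr} UTRs with only {len(genes_sorted)} genes")
    utr_count = 0
    gene_order = list(rng.permutation(len(genes_sorted)))
    for gi in gene_order:
        if utr_count >= n_utr:
            break
        g = genes_sorted[gi]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if g.strand == "+":
            start, end = g.end + 1, g.end + length
        else:
            start, end = g.start - length, g.start - 1
        if not (1 <= start <= end <= truth.genome_length):
            continue
        # must stay intergenic with clearance to the neighbouring gene
        if any(
            other.id != g.id and other.start - clearance <= end and start <= other.end + clearance
            for other in genes_sorted
        ):
            continue
        if not free(start, end):
            continue
        utr_count += 1
        new.planted.append(
            PlantedTranscript(
                id=f"UTR{utr_count:02d}",
                start=start,
                end=end,
                strand=g.strand,
                klass="UTR",
                base_mean=float(rng.uniform(*base_mean_range)),
                host_gene=g.id,
            )
        )
        occupied.append((start, end))
    if utr_count < n_utr:
        raise PlacementError(f"placed only {utr_count}/{n_utr} UTRs; not enough intergenic space")

    # --- sRNAs: fully intergenic with clearance on both sides
    gaps = _gaps(new)
    placed = 0
    attempts = 0
    max_attempts = 500 * max(1, n_srna)
    while placed < n_srna:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(f"placed only {placed}/{n_srna} sRNAs after {attempts} attempts")
        gs, ge = gaps[int(rng.integers(len(gaps)))]
        lo = gs + clearance if gs > 1 else gs
        hi = ge - clearance if ge < truth.genome_length else ge
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if hi - lo + 1 < length:
            continue
        start = int(rng.integers(lo, hi - length + 2))
        end = start + length - 1
        if not free(start, end):
            continue
        placed += 1
        new.planted.append(
            PlantedTranscript(
                id=f"SRNA{placed:02d}",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                klass="sRNA",
                base_mean=float(rng.uniform(*base_mean_range)),
            )
        )
        occupied.append((start, end))
    new.planted.sort(key=lambda p: p.start)
    return new


def assign_fold_changes(
    truth: SyntheticTruth,
    conditions: Sequence[str],
    de_fraction: float = 0.3,
    fold_range: tuple[float, float] = (4.0, 8.0),
    seed: int = 0,
    reference: str | None = None,
) -> SyntheticTruth:
    """Give a random subset of planted features condition-specific fold changes.

    The first condition (or ``reference``) keeps fold 1; each selected
    feature gets, in every other condition, a fold drawn log-uniformly
    from ``fold_range`` with a random direction (up or down).
    """
    if not 0 <= de_fraction <= 1:
        raise DataError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reference = reference or conditions[0]
    n_de = int(round(de_fraction * len(truth.planted)))
    chosen = set(rng.choice(len(truth.planted), size=n_de, replace=False).tolist())
    planted = []
    for i, p in enumerate(truth.planted):
        if i in chosen:
            folds = {}
            for cond in conditions:
                if cond == reference:
                    continue
                f = float(np.exp(rng.uniform(np.log(fold_range[0]), np.log(fold_range[1]))))
                folds[cond] = f if rng.random() < 0.5 else 1.0 / f
            planted.append(dataclasses.replace(p, fold_changes=folds))
        else:
            planted.append(p)
    return dataclasses.replace(truth, planted=planted)


def make_sample_sheet(
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    replicates: int = DEFAULT_REPLICATES,
) -> pd.DataFrame:
    """Sample sheet with ids ``<condition>_r<k>``, indexed by sample id."""
    rows = [
        {"sample": f"{cond}_r{k + 1}", "condition": cond, "replicate": k + 1}
        for cond in conditions
        for k in range(replicates)
    ]
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts_from_means(
    means: pd.DataFrame,
    samples: pd.DataFrame,
    lengths: pd.Series,
    dispersion: float = DEFAULT_DISPERSION,
    library_size_factors: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Draw a negative-binomial count matrix from per-condition means.

    ``means`` is ``features x conditions`` (expected counts per sample at
    library factor 1); each sample's expectation is its condition's mean
    times its library size factor.  Variance is ``mu + phi mu^2``;
    ``phi = 0`` uses Poisson draws.
    """
    if dispersion < 0:
        raise DataError("dispersion must be >= 0")
    factors = {s: 1.0 for s in samples.index}
    if library_size_factors is not None:
        factors.update({k: float(v) for k, v in library_size_factors.items()})
    if any(v <= 0 for v in factors.values()):
        raise DataError("library size factors must be positive")
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(index=means.index, columns=samples.index, dtype=np.int64)
    for s in samples.index:
        cond = samples.loc[s, "condition"]
        if cond not in means.columns:
            raise DataError(f"no expected means for condition {cond!r}")
        mu = means[cond].to_numpy(dtype=float) * factors[s]
        if dispersion == 0:
            counts[s] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            p = r / (r + mu)
            counts[s] = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    return CountMatrix(counts, lengths.reindex(means.index), samples.copy())


def simulate_counts(
    truth: SyntheticTruth,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    replicates_per_condition: int = DEFAULT_REPLICATES,
    library_size_factors: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Simulate per-sample counts for the planted features.

    The expected count of feature *g* in a sample of condition *c* with
    library factor *f* is ``base_mean_g x length_g x fold_g(c) x f``;
    draws are negative binomial with the truth's dispersion.
    """
    if not truth.planted:
        raise DataError("truth has no planted features; call plant_transcripts first")
    samples = make_sample_sheet(conditions, replicates_per_condition)
    means = pd.DataFrame(
        {
            cond: [p.base_mean * p.length * p.fold(cond) for p in truth.planted]
            for cond in conditions
        },
        index=pd.Index([p.id for p in truth.planted], name="feature"),
    )
    lengths = pd.Series({p.id: p.length for p in truth.planted})
    return simulate_counts_from_means(
        means, samples, lengths, truth.dispersion, library_size_factors, seed
    )


def _feature_reads(rng: np.random.Generator, start: int, end: int, n: int, read_length: int) -> np.ndarray:
    """Uniform read start positions keeping reads fully inside [start, end]."""
    length = end - start + 1
    if length <= read_length:
        return np.full(n, start, dtype=np.int64)
    return rng.integers(start, end - read_length + 2, size=n, dtype=np.int64)


def render_coverage(
    truth: SyntheticTruth,
    counts: CountMatrix,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    noise_depth: float = DEFAULT_NOISE_DEPTH,
) -> tuple[dict[str, CoverageTrack], pd.DataFrame]:
    """Turn simulated counts into read intervals and per-sample coverage.

    Each feature's count is laid down as reads of ``read_length`` nt
    whose starts are uniform within the feature; reads never extend past
    the feature (features shorter than a read yield feature-length
    reads), so thresholded coverage stays inside the planted
    coordinates.  Genes additionally receive Poisson reads at the truth's
    ``gene_base_mean`` (reads/nt/sample), and a Poisson background of
    expected per-strand depth ``noise_depth`` is spread over intergenic
    space.  Returns ``(tracks, reads)`` where ``tracks`` maps sample id
    to its :class:`CoverageTrack` and ``reads`` has columns ``start``,
    ``end``, ``strand``, ``sample``.
    """
    if read_length < 1:
        raise DataError("read_length must be >= 1")
    if noise_depth < 0:
        raise DataError("noise_depth must be >= 0")
    rng = np.random.default_rng(seed)
    planted = {p.id: p for p in truth.planted}
    missing = [f for f in counts.features if f not in planted]
    if missing:
        raise DataError(f"counts contain features not in the truth: {missing[:5]}")
    gaps = _gaps(truth)
    gap_lengths = np.array([e - s + 1 for s, e in gaps], dtype=float)
    intergenic_total = float(gap_lengths.sum())

    frames: list[pd.DataFrame] = []
    for sample in counts.counts.columns:
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        strands: list[np.ndarray] = []

        def emit(s: np.ndarray, length: int, strand: str, cap: int) -> None:
            e = np.minimum(s + length - 1, cap)
            starts.append(s)
            ends.append(e)
            strands.append(np.full(len(s), strand, dtype=object))

        for fid, n in counts.counts[sample].items():
            p = planted[fid]
            if n > 0:
                s = _feature_reads(rng, p.start, p.end, int(n), read_length)
                emit(s, min(read_length, p.length), p.strand, p.end)
        for g in truth.genes:
            n = int(rng.poisson(truth.gene_base_mean * g.length))
            if n > 0:
                s = _feature_reads(rng, g.start, g.end, n, read_length)
                emit(s, min(read_length, g.length), g.strand, g.end)
        if noise_depth > 0 and intergenic_total > 0:
            for strand in ("+", "-"):
                n_bg = int(rng.poisson(noise_depth * intergenic_total / read_length))
                if n_bg == 0:
                    continue
                which = rng.choice(len(gaps), size=n_bg, p=gap_lengths / intergenic_total)
                offs = (rng.random(n_bg) * gap_lengths[which]).astype(np.int64)
                s = np.array([gaps[w][0] for w in which], dtype=np.int64) + offs
                emit(s, read_length, strand, truth.genome_length)
        if starts:
            frames.append(
                pd.DataFrame(
                    {
                        "start": np.concatenate(starts),
                        "end": np.concatenate(ends),
                        "strand": np.concatenate(strands),
                        "sample": sample,
                    }
                )
            )
        else:
            frames.append(pd.DataFrame(columns=["start", "end", "strand", "sample"]))

    reads = pd.concat(frames, ignore_index=True)
    reads["start"] = reads["start"].astype(np.int64)
    reads["end"] = reads["end"].astype(np.int64)
    tracks = {
        sample: pileup(
            reads[reads["sample"] == sample], truth.genome_length, sample_ids=[sample]
        )
        for sample in counts.counts.columns
    }
    return tracks, reads


def default_experiment(
    seed: int = 0,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    n_genes: int = DEFAULT_N_GENES,
    n_srna: int = DEFAULT_N_SRNA,
    n_utr: int = DEFAULT_N_UTR,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    replicates: int = DEFAULT_REPLICATES,
    dispersion: float = DEFAULT_DISPERSION,
    de_fraction: float = 0.3,
    read_length: int = DEFAULT_READ_LENGTH,
    noise_depth: float = DEFAULT_NOISE_DEPTH,
) -> tuple[SyntheticTruth, CountMatrix, dict[str, CoverageTrack], pd.DataFrame]:
    """One-call synthetic experiment with the module's default conditions.

    Returns ``(truth, counts, tracks, reads)``.  Sub-seeds are derived
    from ``seed`` so the stages stay individually reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    truth = generate_annotation(genome_length, n_genes, seed=sub[0])
    truth = plant_transcripts(truth, n_srna, n_utr, seed=sub[1])
    truth = dataclasses.replace(truth, dispersion=dispersion, seed=seed)
    truth = assign_fold_changes(truth, conditions, de_fraction=de_fraction, seed=sub[2])
    counts = simulate_counts(truth, conditions, replicates, seed=sub[3])
    tracks, reads = render_coverage(truth, counts, read_length, seed=sub[3], noise_depth=noise_depth)
    return truth, counts, tracks, reads
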