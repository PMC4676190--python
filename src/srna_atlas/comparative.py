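"""Cross-condition analytics for a differential-expression atlas.

Given per-condition sets of significantly changed features (with signs),
this module builds condition-by-condition overlap matrices ("how many
features change in the same direction in both conditions"), row-wise
z-score matrices for heat maps, hierarchical clustering under the
Pearson-correlation distance (d = 1 - r, average linkage), PCA of
replicate-averaged expression profiles, and multi-condition pattern
groups (features changed in at least ``k`` conditions, split into
up-only / down-only / mixed).  A couple of closed-form lab conversions
(growth rate to doubling time, concentration to millimolar) round out
the layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .errors import DataError

UP_ONLY, DOWN_ONLY, MIXED = "up-only", "down-only", "mixed"


# ---------------------------------------------------------------------------
# overlap matrices

@dataclass
class OverlapMatrix:
    """Same-direction DE overlap between conditions.

    ``counts`` is a symmetric integer matrix: the diagonal holds each
    condition's number of significant features; entry (i, j) holds the
    number of features significant in both i and j *with the same sign*.
    ``relative`` is row-normalized by the row condition's diagonal count
    (0 rows stay 0).
    """

    counts: pd.DataFrame
    relative: pd.DataFrame


def overlap_matrix(de_sets: Mapping[str, pd.Series]) -> OverlapMatrix:
    """Build the overlap matrix from per-condition signed DE sets.

    ``de_sets`` maps a condition name to a Series of +1/-1 indexed by
    feature (only significant features present).
    """
    conds = list(de_sets)
    n = len(conds)
    counts = np.zeros((n, n), dtype=np.int64)
    for i, ci in enumerate(conds):
        si = de_sets[ci]
        counts[i, i] = len(si)
        for j in range(i + 1, n):
            sj = de_sets[conds[j]]
            shared = si.index.intersection(sj.index)
            same = int((si[shared] == sj[shared]).sum())
            counts[i, j] = counts[j, i] = same
    cdf = pd.DataFrame(counts, index=conds, columns=conds)
    diag = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(diag[:, None] > 0, counts / diag[:, None], 0.0)
    np.fill_diagonal(rel, np.where(diag > 0, 1.0, 0.0))
    return OverlapMatrix(cdf, pd.DataFrame(rel, index=conds, columns=conds))


def percent_de(n_signif: int, n_total: int) -> float:
    """Percentage of significant features, printed-style (1 decimal).

    Rounds half away from zero, e.g. (76, 462) -> 16.5.
    """
    if n_total <= 0:
        raise DataError("n_total must be > 0")
    if not 0 <= n_signif <= n_total:
        raise DataError("n_signif must lie in [0, n_total]")
    value = Decimal(100 * n_signif) / Decimal(n_total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# heat-map standardization and clustering

def zscore_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Standardize each row to mean 0 and (sample, ddof=1) sd 1.

    Rows with zero variance cannot be standardized; they are dropped and
    returned separately.  Re-standardizing the output is a no-op.
    """
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return (
        pd.DataFrame(z, index=expr.index[keep], columns=expr.columns),
        expr.index[~keep],
    )


def pearson_distance(matrix: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Pairwise Pearson-correlation distance d = 1 - r between profiles."""
    profiles = matrix if axis == "index" else matrix.T
    r = np.corrcoef(profiles.to_numpy(dtype=float))
    if np.isnan(r).any():
        raise DataError("constant profiles have undefined Pearson correlation")
    labels = profiles.index
    return pd.DataFrame(1.0 - r, index=labels, columns=labels)


@dataclass
class ClusterResult:
    """Average-linkage dendrogram under a precomputed distance.

    ``linkage`` follows the scipy convention: row k merges clusters
    ``linkage[k, 0]`` and ``linkage[k, 1]`` (ids < n are leaves) at
    height ``linkage[k, 2]`` into cluster ``n + k`` of size
    ``linkage[k, 3]``.
    """

    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    merge_heights: list[float]

    def newick(self) -> str:
        """Ultrametric Newick string (leaf heights 0, node height = d/2)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, d, _size) in enumerate(self.linkage):
            a, b = int(a), int(b)
            h = d / 2.0
            node[n + k] = (
                f"({node[a]}:{h - height[a]:.6g},{node[b]}:{h - height[b]:.6g})"
            )
            height[n + k] = h
        return node[n + len(self.merge_heights) - 1] + ";" if n > 1 else node[0] + ";"


def pearson_cluster(matrix: pd.DataFrame, axis: str = "columns") -> ClusterResult:
    """Agglomerative clustering with d = 1 - r and average linkage.

    Deterministic: at every step the pair at minimal distance is merged,
    with exact ties broken in favour of the pair whose member clusters
    contain the smallest leaf index.  Leaf order lists, within each
    merged node, the child containing the smaller leaf index first.
    """
    dist = pearson_distance(matrix, axis=axis)
    labels = list(dist.index.astype(str))
    n = len(labels)
    if n < 2:
        raise DataError("clustering needs at least 2 profiles")
    d = {
        (i, j): float(dist.iat[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    active = set(range(n))
    linkage = np.zeros((n - 1, 4))
    heights: list[float] = []
    next_id = n
    for step in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = d[(min(i, j), max(i, j))]
                key = (dij, min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_key, a, b) = best
        dab = d[(min(a, b), max(a, b))]
        na, nb = len(members[a]), len(members[b])
        for k in active:
            if k in (a, b):
                continue
            dka = d[(min(k, a), max(k, a))]
            dkb = d[(min(k, b), max(k, b))]
            d[(min(k, next_id), max(k, next_id))] = (na * dka + nb * dkb) / (na + nb)
        members[next_id] = members[a] + members[b]
        min_leaf[next_id] = min(min_leaf[a], min_leaf[b])
        children[next_id] = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        linkage[step] = (min(a, b), max(a, b), dab, na + nb)
        heights.append(dab)
        active.discard(a)
        active.discard(b)
        active.add(next_id)
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return leaves(left) + leaves(right)

    order = [labels[i] for i in leaves(next_id - 1)]
    return ClusterResult(labels, linkage, order, heights)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_fraction: pd.Series


def pca(expr: pd.DataFrame) -> PCAResult:
    """Centered (not scaled) PCA of expression profiles.

    ``expr`` is features x samples with samples as the observations
    (typically replicate-averaged normalized log expression).  Variance
    fractions over all returned components sum to 1; components are
    ordered by decreasing variance.  Requires at least two samples.
    """
    if expr.shape[1] < 2:
        raise DataError("PCA needs at least 2 samples")
    x = expr.to_numpy(dtype=float).T  # samples x features
    model = _SKPCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(x)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=comps),
        loadings=pd.DataFrame(model.components_.T, index=expr.index, columns=comps),
        variance_fraction=pd.Series(model.explained_variance_ratio_, index=comps),
    )


# ---------------------------------------------------------------------------
# multi-condition pattern groups

def pattern_groups(
    de_sets: Mapping[str, pd.Series],
    max_mev: pd.Series | None = None,
    min_conditions: int = 4,
    mev_threshold: float = 1.0,
) -> pd.DataFrame:
    """Group features by their multi-condition direction patterns.

    ``de_sets`` maps condition name to a +1/-1 Series over that
    condition's significant features.  For every feature significant
    anywhere, the result records the number of significant conditions,
    the per-condition direction columns, the pattern group (``up-only``,
    ``down-only`` or ``mixed`` — exhaustive and exclusive over the sign
    multiset), the maximum condition-specific MEV (when ``max_mev`` is
    given) and a ``selected`` flag requiring significance in at least
    ``min_conditions`` conditions and max MEV >= ``mev_threshold``.
    """
    if min_conditions < 1:
        raise DataError("min_conditions must be >= 1")
    features: pd.Index = pd.Index([])
    for s in de_sets.values():
        features = features.union(s.index)
    rows = []
    for feat in features:
        dirs = {c: int(s.get(feat, 0)) for c, s in de_sets.items()}
        signs = [v for v in dirs.values() if v != 0]
        n_sig = len(signs)
        if all(v > 0 for v in signs):
            group = UP_ONLY
        elif all(v < 0 for v in signs):
            group = DOWN_ONLY
        else:
            group = MIXED
        mev_val = float(max_mev.get(feat, np.nan)) if max_mev is not None else np.nan
        selected = n_sig >= min_conditions and (
            max_mev is None or (not math.isnan(mev_val) and mev_val >= mev_threshold)
        )
        rows.append({"feature": feat, "n_significant": n_sig, "group": group,
                     "max_mev": mev_val, "selected": selected, **dirs})
    out = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["n_significant", "group", "max_mev", "selected"]
    )
    return out


# ---------------------------------------------------------------------------
# closed-form lab conversions

def doubling_time(growth_rate: float) -> float:
    """Doubling time in hours from an exponential growth rate (per hour)."""
    if growth_rate <= 0:
        raise DataError("growth_rate must be > 0")
    return math.log(2.0) / growth_rate


def to_millimolar(
    amount: float,
    molar_mass: float,
    density: float | None = None,
    unit: str = "g_per_l",
) -> float:
    """Convert a concentration to millimolar.

    ``unit="g_per_l"``: amount is grams per liter; mM = 1000 * (g/L) / M.
    ``unit="percent_v_v"``: amount is % (v/v) and requires the liquid's
    density in g/mL; mM = 1000 * (10 * percent * density) / M.
    Molar masses and densities are caller-supplied; nothing chemical is
    hard-coded.
    """
    if molar_mass <= 0:
        raise DataError("molar_mass must be > 0")
    if amount < 0:
        raise DataError("amount must be >= 0")
    if unit == "g_per_l":
        grams_per_l = amount
    elif unit == "percent_v_v":
        if density is None:
            raise DataError("density (g/mL) is required for %v/v conversions")
        grams_per_l = 10.0 * amount * density
    else:
        raise DataError(f"unknown unit {unit!r}")
    return 1000.0 * grams_per_l / molar_mass
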