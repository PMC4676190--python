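"""Overlap matrices, clustering, PCA, pattern groups and unit conversions."""

import math

import numpy as np
import pandas as pd
import pytest

from srna_atlas import comparative
from srna_atlas.errors import DataError


def signed(mapping: dict[str, int]) -> pd.Series:
    return pd.Series(mapping, dtype=int)


# ---------------------------------------------------------------------------
# overlap matrix

def test_disjoint_sets_have_zero_off_diagonals():
    ov = comparative.overlap_matrix(
        {"a": signed({"f1": 1, "f2": -1}), "b": signed({"f3": 1})}
    )
    assert ov.counts.loc["a", "a"] == 2 and ov.counts.loc["b", "b"] == 1
    assert ov.counts.loc["a", "b"] == 0


def test_identical_sets_same_signs_fill_off_diagonal():
    s = signed({"f1": 1, "f2": -1, "f3": 1})
    ov = comparative.overlap_matrix({"a": s, "b": s.copy()})
    assert ov.counts.loc["a", "b"] == 3
    assert ov.relative.loc["a", "b"] == 1.0


def test_opposite_signs_do_not_count():
    ov = comparative.overlap_matrix(
        {"a": signed({"f1": 1, "f2": 1}), "b": signed({"f1": -1, "f2": 1})}
    )
    assert ov.counts.loc["a", "b"] == 1  # only f2 agrees in direction


def test_overlap_matrix_symmetry_and_bounds_on_random_sets():
    rng = np.random.default_rng(6)
    features = [f"f{i}" for i in range(40)]
    de_sets = {}
    for c in "abcde":
        chosen = rng.choice(features, size=rng.integers(0, 30), replace=False)
        de_sets[c] = signed({f: int(rng.choice([-1, 1])) for f in chosen})
    ov = comparative.overlap_matrix(de_sets)
    m = ov.counts.to_numpy()
    assert (m == m.T).all()
    diag = np.diag(m)
    for i in range(5):
        for j in range(5):
            if i != j:
                assert m[i, j] <= min(diag[i], diag[j])
    assert ((ov.relative.to_numpy() >= 0) & (ov.relative.to_numpy() <= 1)).all()


# ---------------------------------------------------------------------------
# percentage rounding

@pytest.mark.parametrize(
    "n,total,expected",
    [(76, 462, 16.5), (138, 462, 29.9), (177, 462, 38.3), (44, 462, 9.5), (84, 462, 18.2), (0, 462, 0.0)],
)
def test_percent_de_reproduces_printed_fractions(n, total, expected):
    assert comparative.percent_de(n, total) == expected


def test_percent_de_rounds_half_away_from_zero():
    assert comparative.percent_de(1, 800) == 0.1  # 0.125 -> 0.1
    assert comparative.percent_de(3, 2000) == 0.2  # 0.15 -> 0.2 (half away)


# ---------------------------------------------------------------------------
# z-scores

def test_zscore_rows_standardized_and_constant_rows_dropped():
    expr = pd.DataFrame(
        {"s1": [1.0, 5.0, 2.0], "s2": [3.0, 5.0, 4.0], "s3": [5.0, 5.0, 9.0]},
        index=["a", "flat", "b"],
    )
    z, dropped = comparative.zscore_matrix(expr)
    assert list(dropped) == ["flat"]
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0)
    # two-point row standardizes to +-1/sqrt(2) under the ddof=1 convention
    two = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["r"])
    z2, _ = comparative.zscore_matrix(two)
    np.testing.assert_allclose(z2.loc["r"].to_numpy(), [-math.sqrt(0.5), math.sqrt(0.5)])


def test_zscore_is_idempotent():
    rng = np.random.default_rng(4)
    expr = pd.DataFrame(rng.normal(size=(20, 6)))
    z1, _ = comparative.zscore_matrix(expr)
    z2, _ = comparative.zscore_matrix(z1)
    np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# clustering

def brute_force_average_linkage(dist: pd.DataFrame):
    """Agglomerate by recomputing mean inter-cluster distance from scratch."""
    n = len(dist)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                d = float(
                    np.mean([dist.iat[i, j] for i in clusters[a] for j in clusters[b]])
                )
                key = (d, min(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (key, a, b) = best
        merges.append((sorted(clusters[a] + clusters[b]), key[0]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_identical_profiles_merge_first_at_distance_zero():
    expr = pd.DataFrame(
        {"a": [1.0, 2, 3, 1], "b": [2.0, 4, 6, 2], "c": [5.0, 1, 0, 7]}
    )
    res = comparative.pearson_cluster(expr, axis="columns")
    # a and b are perfectly correlated -> d = 0, merged in the first step
    assert res.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
    assert set(res.linkage[0, :2].astype(int)) == {0, 1}


def test_anticorrelated_profiles_at_distance_two():
    expr = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
    d = comparative.pearson_distance(expr, axis="columns")
    assert d.loc["a", "b"] == pytest.approx(2.0)


def test_agglomeration_matches_brute_force_on_five_profiles():
    rng = np.random.default_rng(15)
    expr = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
    res = comparative.pearson_cluster(expr, axis="columns")
    dist = comparative.pearson_distance(expr, axis="columns")
    expected = brute_force_average_linkage(dist)
    assert len(res.merge_heights) == len(expected)
    for height, (_members, exp_height) in zip(res.merge_heights, expected):
        assert height == pytest.approx(exp_height, abs=1e-12)
    # same partition sequence
    n = 5
    members = {i: [i] for i in range(n)}
    for step, (a, b, _d, _size) in enumerate(res.linkage):
        merged = sorted(members[int(a)] + members[int(b)])
        assert merged == expected[step][0]
        members[n + step] = merged


def test_cluster_matches_scipy_average_linkage():
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(16)
    expr = pd.DataFrame(rng.normal(size=(30, 8)))
    res = comparative.pearson_cluster(expr, axis="columns")
    dist = comparative.pearson_distance(expr, axis="columns")
    z = linkage(squareform(dist.to_numpy(), checks=False), method="average")
    np.testing.assert_allclose(sorted(res.merge_heights), sorted(z[:, 2]), atol=1e-10)


def test_newick_contains_all_leaves():
    rng = np.random.default_rng(17)
    expr = pd.DataFrame(rng.normal(size=(10, 4)), columns=["w", "x", "y", "z"])
    res = comparative.pearson_cluster(expr, axis="columns")
    nwk = res.newick()
    assert nwk.endswith(";") and all(leaf in nwk for leaf in ["w", "x", "y", "z"])
    assert sorted(res.leaf_order) == ["w", "x", "y", "z"]


# ---------------------------------------------------------------------------
# PCA

def test_pca_rejects_single_sample():
    with pytest.raises(DataError):
        comparative.pca(pd.DataFrame({"s1": [1.0, 2.0]}))


def test_pca_variance_fractions_and_duplicate_samples():
    rng = np.random.default_rng(18)
    expr = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    expr["e"] = expr["d"]  # duplicated sample
    res = comparative.pca(expr)
    assert res.variance_fraction.sum() == pytest.approx(1.0)
    assert (res.variance_fraction.diff().dropna() <= 1e-12).all()
    np.testing.assert_allclose(
        res.scores.loc["d"].to_numpy(), res.scores.loc["e"].to_numpy(), atol=1e-9
    )
    # full reconstruction from all components
    centered = expr.T - expr.T.mean(axis=0)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    np.testing.assert_allclose(recon, centered.to_numpy(), atol=1e-9)


def test_pca_scores_invariant_to_feature_order_up_to_sign():
    rng = np.random.default_rng(19)
    expr = pd.DataFrame(rng.normal(size=(40, 6)))
    res1 = comparative.pca(expr)
    shuffled = expr.sample(frac=1.0, random_state=1)
    res2 = comparative.pca(shuffled)
    for pc in res1.scores.columns[:3]:
        a, b = res1.scores[pc].to_numpy(), res2.scores[pc].to_numpy()
        assert np.allclose(a, b, atol=1e-9) or np.allclose(a, -b, atol=1e-9)


# ---------------------------------------------------------------------------
# pattern groups

def test_pattern_group_assignment_and_selection():
    de_sets = {f"c{i}": signed({}) for i in range(13)}
    de_sets["c0"] = signed({"up5": 1, "mix": 1, "three": 1})
    de_sets["c1"] = signed({"up5": 1, "mix": 1, "three": 1})
    de_sets["c2"] = signed({"up5": 1, "mix": 1, "three": 1})
    de_sets["c3"] = signed({"up5": 1, "mix": -1})
    de_sets["c4"] = signed({"up5": 1})
    mev = pd.Series({"up5": 50.0, "mix": 3.0, "three": 9.0})
    groups = comparative.pattern_groups(de_sets, mev, min_conditions=4)
    assert groups.loc["up5", "group"] == comparative.UP_ONLY
    assert bool(groups.loc["up5", "selected"])
    assert groups.loc["mix", "group"] == comparative.MIXED
    assert bool(groups.loc["mix", "selected"])  # 3 up + 1 down = 4 conditions
    assert groups.loc["three", "n_significant"] == 3
    assert not bool(groups.loc["three", "selected"])


def test_low_mev_features_are_not_selected():
    de_sets = {f"c{i}": signed({"f": -1}) for i in range(5)}
    groups = comparative.pattern_groups(de_sets, pd.Series({"f": 0.4}), min_conditions=4)
    assert groups.loc["f", "group"] == comparative.DOWN_ONLY
    assert not bool(groups.loc["f", "selected"])


def test_pattern_groups_partition_selected_features():
    rng = np.random.default_rng(20)
    features = [f"f{i}" for i in range(60)]
    de_sets = {}
    for c in range(13):
        chosen = rng.choice(features, size=30, replace=False)
        de_sets[f"c{c}"] = signed({f: int(rng.choice([-1, 1])) for f in chosen})
    mev = pd.Series(10.0, index=features)
    groups = comparative.pattern_groups(de_sets, mev, min_conditions=4)
    sel = groups[groups["selected"]]
    counts = sel["group"].value_counts()
    assert counts.sum() == len(sel)
    assert set(counts.index) <= {comparative.UP_ONLY, comparative.DOWN_ONLY, comparative.MIXED}


# ---------------------------------------------------------------------------
# conversions

def test_doubling_time_closed_form():
    assert round(comparative.doubling_time(0.14)) == 5
    assert comparative.doubling_time(math.log(2)) == pytest.approx(1.0)
    rng = np.random.default_rng(21)
    for mu in rng.uniform(0.01, 3.0, 20):
        assert mu * comparative.doubling_time(mu) == pytest.approx(math.log(2))


@pytest.mark.parametrize(
    "grams_per_l,molar_mass,expected_mm",
    [(3.0, 105.09, 29), (32.0, 118.09, 271), (29.0, 130.10, 223), (0.0, 105.09, 0)],
)
def test_mass_concentration_to_millimolar(grams_per_l, molar_mass, expected_mm):
    assert round(comparative.to_millimolar(grams_per_l, molar_mass)) == expected_mm


def test_percent_vv_conversion_requires_density():
    with pytest.raises(DataError, match="density"):
        comparative.to_millimolar(0.75, 74.12, unit="percent_v_v")
    # 0.75 %v/v butanol, density 0.81 g/mL, M = 74.12 -> ~82 mM
    assert round(comparative.to_millimolar(0.75, 74.12, density=0.81, unit="percent_v_v")) == 82
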