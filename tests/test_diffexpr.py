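"""Normalization and NB testing: oracles, calibration and invariances."""

import subprocess
import sys
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srna_atlas import diffexpr, synthetic
from srna_atlas.diffexpr import NormalizationFactors
from srna_atlas.quantify import CountMatrix


def cm_from(counts: pd.DataFrame, conditions: list[str], lengths: int = 100) -> CountMatrix:
    samples = pd.DataFrame({"condition": conditions}, index=counts.columns)
    return CountMatrix(counts, pd.Series(lengths, index=counts.index), samples)


# ---------------------------------------------------------------------------
# TMM

def test_identical_libraries_have_unit_factors():
    rng = np.random.default_rng(1)
    col = rng.poisson(80, 100)
    counts = pd.DataFrame({"a": col, "b": col, "c": col}, index=[f"g{i}" for i in range(100)])
    f = diffexpr.tmm_factors(cm_from(counts, ["x", "x", "y"]))
    assert (f.factors == 1.0).all()


def test_depth_difference_is_absorbed_by_library_size():
    rng = np.random.default_rng(2)
    col = rng.poisson(80, 200) + 1
    counts = pd.DataFrame({"a": col, "b": col * 2}, index=[f"g{i}" for i in range(200)])
    f = diffexpr.tmm_factors(cm_from(counts, ["x", "y"]))
    assert np.allclose(f.factors, 1.0)


def test_tmm_matches_hand_computed_five_feature_oracle():
    """Frozen trim-and-weighted-mean computation, executed by hand beforehand."""
    counts = pd.DataFrame(
        {"A": [100, 200, 300, 450, 500], "B": [80, 500, 300, 400, 1000]},
        index=[f"f{i}" for i in range(5)],
    )
    f = diffexpr.tmm_factors(cm_from(counts, ["x", "y"]), reference="B")
    assert abs(f.factors["A"] - 1.0244987480929795) < 1e-9
    assert abs(f.factors["B"] - 0.9760870883067626) < 1e-9


def test_tmm_matches_edger_on_random_matrix(tmp_path):
    """Independent cross-check against the reference TMM implementation in R."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(rng.uniform(5, 400, size=(300, 1)), size=(300, 4)),
        columns=list("ABCD"),
        index=[f"f{i}" for i in range(300)],
    )
    ours = diffexpr.tmm_factors(cm_from(counts, ["x", "x", "y", "y"])).factors
    tsv = tmp_path / "counts.tsv"
    counts.to_csv(tsv, sep="\t")
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.delim("{tsv}", row.names=1));'
        'cat(sprintf("%.10f\\n", calcNormFactors(x, method="TMM")))'
    )
    res = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True, timeout=300
    )
    theirs = np.array([float(v) for v in res.stdout.split()])
    np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-6)


def test_tmm_corrects_composition_bias():
    """30% of features doubled in one library: factors near the analytic truth."""
    rng = np.random.default_rng(11)
    base = rng.uniform(50, 500, 1000)
    a = rng.poisson(base)
    b = rng.poisson(np.where(np.arange(1000) < 300, 2.0, 1.0) * base)
    counts = pd.DataFrame({"A": a, "B": b}, index=[f"g{i}" for i in range(1000)])
    f = diffexpr.tmm_factors(cm_from(counts, ["x", "y"]))
    truth = np.array([np.sqrt(1.3), 1 / np.sqrt(1.3)])
    np.testing.assert_allclose(f.factors[["A", "B"]].to_numpy(), truth, rtol=0.05)


# ---------------------------------------------------------------------------
# dispersion

def test_constant_counts_give_zero_dispersion():
    counts = pd.DataFrame({"a": [50] * 20, "b": [50] * 20, "c": [50] * 20})
    counts.index = [f"g{i}" for i in range(20)]
    est = diffexpr.estimate_dispersion(cm_from(counts, ["x", "x", "x"]))
    assert est.common == 0.0


def test_poisson_data_give_near_zero_dispersion():
    rng = np.random.default_rng(8)
    mu = rng.uniform(50, 500, 2000)
    counts = pd.DataFrame(
        {f"s{i}": rng.poisson(mu) for i in range(3)}, index=[f"g{i}" for i in range(2000)]
    )
    est = diffexpr.estimate_dispersion(cm_from(counts, ["x"] * 3))
    assert est.common <= 0.05


def test_nb_dispersion_recovered_from_simulation():
    rng = np.random.default_rng(9)
    mu = rng.uniform(50, 500, 2000)
    phi = 0.4
    r = 1 / phi
    counts = pd.DataFrame(
        {f"s{i}": rng.negative_binomial(r, r / (r + mu)) for i in range(3)},
        index=[f"g{i}" for i in range(2000)],
    )
    est = diffexpr.estimate_dispersion(cm_from(counts, ["x"] * 3))
    assert 0.3 <= est.common <= 0.5


def test_unreplicated_design_warns_and_uses_poisson():
    counts = pd.DataFrame({"a": [10] * 5, "b": [12] * 5}, index=[f"g{i}" for i in range(5)])
    with pytest.warns(UserWarning, match="no condition has replicates"):
        est = diffexpr.estimate_dispersion(cm_from(counts, ["x", "y"]))
    assert est.common == 0.0


# ---------------------------------------------------------------------------
# exact test

def brute_force_conditional_binomial(s_a: int, t: int, n_a: int, n_b: int) -> Fraction:
    """Exact rational two-sided p by enumerating every split of the total."""
    pi_num, pi_den = n_a, n_a + n_b
    probs = [
        Fraction(comb(t, s) * pi_num**s * (pi_den - pi_num) ** (t - s), pi_den**t)
        for s in range(t + 1)
    ]
    obs = probs[s_a]
    return sum(p for p in probs if p <= obs)


def test_equal_sums_equal_sizes_give_p_one(toy_count_matrix):
    cm = toy_count_matrix
    cm.counts.loc[:, :] = 40  # every sample identical
    unit = NormalizationFactors(
        pd.Series(1.0, index=cm.counts.columns), cm.counts.columns[0],
        cm.library_sizes().astype(float),
    )
    p = diffexpr.nb_exact_test(cm, unit, 0.0, ("x", "y"))
    assert (p == 1.0).all()


def test_zero_total_gives_p_one(toy_count_matrix):
    cm = toy_count_matrix
    cm.counts.iloc[0] = 0
    unit = NormalizationFactors(
        pd.Series(1.0, index=cm.counts.columns), cm.counts.columns[0],
        cm.library_sizes().astype(float),
    )
    p = diffexpr.nb_exact_test(cm, unit, 0.1, ("x", "y"))
    assert p.iloc[0] == 1.0


@pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 2), (3, 2)])
def test_poisson_exact_test_matches_rational_enumeration(n_a, n_b):
    from srna_atlas.diffexpr import _exact_pvalue

    for t in range(0, 31):
        for s_a in range(t + 1):
            expected = float(brute_force_conditional_binomial(s_a, t, n_a, n_b))
            got = _exact_pvalue(s_a, t, n_a, n_b, 0.0)
            assert abs(got - expected) < 1e-9, (s_a, t, n_a, n_b)


def test_null_pvalues_are_approximately_uniform():
    rng = np.random.default_rng(100)
    idx = [f"g{i}" for i in range(2000)]
    means = pd.DataFrame({"x": rng.uniform(100, 500, 2000)}, index=idx)
    means["y"] = means["x"]
    cm = synthetic.simulate_counts_from_means(
        means, synthetic.make_sample_sheet(["x", "y"], 3),
        pd.Series(100, index=idx), dispersion=0.1, seed=77,
    )
    res = diffexpr.de_test(cm, ("x", "y"))
    from scipy.stats import kstest

    assert kstest(res.table["pvalue"], "uniform").statistic < 0.05


def test_identical_libraries_yield_no_significant_features():
    rng = np.random.default_rng(3)
    col = rng.poisson(100, 500)
    counts = pd.DataFrame({f"s{i}": col for i in range(6)}, index=[f"g{i}" for i in range(500)])
    res = diffexpr.de_test(cm_from(counts, ["x"] * 3 + ["y"] * 3), ("x", "y"))
    assert int((res.table["qvalue"] < 0.05).sum()) == 0


# ---------------------------------------------------------------------------
# BH FDR

def brute_force_bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            m * p[j] / (r + 1)
            for r, j in enumerate(order)
            if r + 1 >= rank
        )
    return np.minimum(q, 1.0)


def test_bh_trivial_cases():
    assert diffexpr.bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)
    q = diffexpr.bh_fdr(np.array([0.01, 0.02, 0.03]))
    np.testing.assert_allclose(q, [0.03, 0.03, 0.03])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_matches_brute_force_definition(pvals):
    p = np.array(pvals)
    np.testing.assert_allclose(diffexpr.bh_fdr(p), brute_force_bh(p), atol=1e-12)


# ---------------------------------------------------------------------------
# fold changes

def test_fold_change_examples(toy_count_matrix):
    cm = toy_count_matrix
    # equal factors and equal library sizes: normalization is neutral
    unit = NormalizationFactors(
        pd.Series(1.0, index=cm.counts.columns), cm.counts.columns[0],
        pd.Series(1000.0, index=cm.counts.columns),
    )
    cm.counts.loc[:, :] = 100
    assert np.allclose(diffexpr.fold_change(cm, unit, ("x", "y")), 0.0)
    cm.counts.loc[:, cm.samples_for("x")] = 40
    cm.counts.loc[:, cm.samples_for("y")] = 10
    lfc = diffexpr.fold_change(cm, unit, ("x", "y"))
    assert np.allclose(lfc, np.log2(40.5 / 10.5))  # prior count 0.5 per group mean
    assert np.all(np.abs(lfc - 2.0) < 0.1)


def test_planted_fold_changes_recovered():
    rng = np.random.default_rng(12)
    idx = [f"g{i}" for i in range(500)]
    means = pd.DataFrame({"x": rng.uniform(100, 400, 500)}, index=idx)
    means["y"] = means["x"]
    means.iloc[:100, 1] *= 4.0
    cm = synthetic.simulate_counts_from_means(
        means, synthetic.make_sample_sheet(["x", "y"], 3),
        pd.Series(100, index=idx), dispersion=0.1, seed=13,
    )
    factors = diffexpr.tmm_factors(cm)
    lfc = diffexpr.fold_change(cm, factors, ("y", "x"))
    assert np.abs(lfc.iloc[:100] - 2.0).mean() < 0.5
    assert np.abs(lfc.iloc[100:]).mean() < 0.5


def test_qvalues_invariant_to_scaling_one_sample():
    """phi = 0, fixed unit factors: depth changes are absorbed by library size."""
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        rng.poisson(100, size=(300, 6)),
        columns=[f"s{i}" for i in range(6)],
        index=[f"g{i}" for i in range(300)],
    )
    conds = ["x"] * 3 + ["y"] * 3

    def qvals(c: pd.DataFrame) -> pd.Series:
        cm = cm_from(c, conds)
        unit = NormalizationFactors(
            pd.Series(1.0, index=c.columns), "s0", cm.library_sizes().astype(float)
        )
        return diffexpr.de_test(cm, ("x", "y"), factors=unit, dispersion=0.0).table["qvalue"]

    scaled = counts.copy()
    scaled["s3"] = scaled["s3"] * 7  # not the reference sample
    assert (qvals(counts) - qvals(scaled)).abs().max() < 1e-9


def test_fraction_high_fold():
    table = pd.DataFrame(
        {
            "log2fc": [2.5, -2.1, 0.5, 3.0],
            "pvalue": [0.001] * 4,
            "qvalue": [0.001, 0.001, 0.001, 0.2],
            "direction": ["up", "down", "up", "ns"],
        },
        index=list("abcd"),
    )
    de = diffexpr.DEResult(("x", "y"), table)
    assert diffexpr.fraction_high_fold(de, 4.0) == pytest.approx(2 / 3)
    empty = diffexpr.DEResult(("x", "y"), table.assign(qvalue=1.0))
    assert diffexpr.fraction_high_fold(empty) is None
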