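"""TMM normalization and negative-binomial two-group testing.

Normalization follows the trimmed mean of M-values (TMM) method: for each
library against a reference, per-feature log2 expression ratios (M) and
average log2 abundances (A) are computed on counts relative to library
size, the extremes are trimmed (30 % by M, 5 % by A), and the scaling
factor is two to the power of the precision-weighted mean of the
surviving M values, with weights given by the inverse asymptotic
(delta-method binomial) variance ``1/y - 1/N + 1/y_r - 1/N_r``.  Factors
are rescaled to geometric mean 1.

Testing treats counts as negative binomial with variance
``mu + phi mu^2``.  For a two-group contrast, replicate counts are scaled
to the reference sample's effective library size (``factor x library
size``), summed per group, and the p-value is the probability, under the
NB model conditioned on the feature's total, of group splits with
probability at most that of the observed split (a two-sided exact test by
summed probabilities; ``phi = 0`` reduces to the conditional binomial
test).  All contrasts are pairwise, so no GLM machinery is needed;
multiple testing is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .quantify import CountMatrix

UP, DOWN, NS = "up", "down", "ns"
DEFAULT_LOGRATIO_TRIM = 0.30
DEFAULT_ABUNDANCE_TRIM = 0.05
DEFAULT_PRIOR_REPLICATES = 10.0
DEFAULT_ALPHA = 0.05
DEFAULT_PRIOR_COUNT = 0.5


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors.

    ``factors`` have geometric mean 1; a sample's *effective* library
    size is ``factor x library size``.  ``reference`` is the sample all
    pairwise M/A computations used.
    """

    factors: pd.Series
    reference: str
    library_sizes: pd.Series
    logratio_trim: float = DEFAULT_LOGRATIO_TRIM
    abundance_trim: float = DEFAULT_ABUNDANCE_TRIM

    def effective_sizes(self) -> pd.Series:
        return self.factors * self.library_sizes

    def reference_effective_size(self) -> float:
        return float(self.effective_sizes()[self.reference])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abundance_trim: float,
) -> float:
    """TMM factor of one library against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[finite], abs_e[finite], var[finite]
    if log_r.size == 0:
        warnings.warn("no features survive the M/A computation; TMM factor set to 1")
        return 1.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_r)
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        warnings.warn("trimming removed every feature; TMM factor set to 1")
        return 1.0
    w = 1.0 / var[keep]
    return float(2.0 ** (np.sum(w * log_r[keep]) / np.sum(w)))


def tmm_factors(
    cm: CountMatrix,
    reference: str | None = None,
    logratio_trim: float = DEFAULT_LOGRATIO_TRIM,
    abundance_trim: float = DEFAULT_ABUNDANCE_TRIM,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors for every sample.

    With ``reference=None`` the reference library is the one whose
    upper-quartile relative abundance (75th percentile of counts divided
    by library size) is closest to the mean across samples.  Features
    with a zero count in either library of a pair drop out of that
    pair's M/A computation.
    """
    if cm.counts.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    counts = cm.counts.loc[cm.counts.sum(axis=1) > 0]
    lib = cm.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise DataError("a library has zero total counts")
    if reference is None:
        uq = counts.apply(lambda col: np.quantile(col.to_numpy(dtype=float), 0.75), axis=0) / lib
        reference = (uq - uq.mean()).abs().idxmin()
    elif reference not in cm.counts.columns:
        raise DataError(f"reference sample {reference!r} not in the count matrix")
    ref = counts[reference].to_numpy(dtype=float)
    n_ref = float(lib[reference])
    f = {}
    for s in cm.counts.columns:
        if s == reference:
            f[s] = 1.0
        else:
            f[s] = _tmm_pair(
                counts[s].to_numpy(dtype=float), ref, float(lib[s]), n_ref,
                logratio_trim, abundance_trim,
            )
    factors = pd.Series(f)[cm.counts.columns]
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(factors, reference, lib, logratio_trim, abundance_trim)


@dataclass
class DispersionEstimate:
    """Common and per-feature NB dispersions (variance = mu + phi mu^2)."""

    common: float
    per_feature: pd.Series
    residual_df: int


def _normalized(cm: CountMatrix, factors: NormalizationFactors | None) -> tuple[pd.DataFrame, NormalizationFactors]:
    factors = factors or tmm_factors(cm)
    eff = factors.effective_sizes()
    target = factors.reference_effective_size()
    return cm.counts / eff * target, factors


def estimate_dispersion(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    prior_replicates: float = DEFAULT_PRIOR_REPLICATES,
) -> DispersionEstimate:
    """Method-of-moments dispersion from within-condition variability.

    On counts scaled to a common effective library size, each feature and
    replicated condition contribute a moment pair (mean m, variance v);
    the common dispersion pools them as
    ``sum(v - m) / sum(m^2 - v/n)`` (the denominator is the unbiased
    estimate of mu^2), floored at 0.  Per-feature estimates are shrunk
    toward the common value with weight ``d / (d + n0)`` where ``d`` is
    the feature's residual degrees of freedom and ``n0`` the prior
    replicate count (default 10).  With no replicated condition the
    dispersion is fixed to 0 with a loud warning.
    """
    norm, factors = _normalized(cm, factors)
    conditions = cm.conditions
    num_common = 0.0
    den_common = 0.0
    num_g = np.zeros(len(norm.index))
    den_g = np.zeros(len(norm.index))
    df = 0
    for cond in conditions:
        cols = cm.samples_for(cond)
        n = len(cols)
        if n < 2:
            continue
        block = norm[cols].to_numpy(dtype=float)
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        num = v - m
        den = m * m - v / n
        ok = den > 0
        num_common += float(num[ok].sum())
        den_common += float(den[ok].sum())
        num_g[ok] += num[ok]
        den_g[ok] += den[ok]
        df += (n - 1) * 1
    if df == 0:
        warnings.warn(
            "no condition has replicates: dispersion fixed to 0 (Poisson); "
            "p-values will be anti-conservative if counts are overdispersed",
            stacklevel=2,
        )
        return DispersionEstimate(0.0, pd.Series(0.0, index=cm.features), 0)
    common = max(0.0, num_common / den_common) if den_common > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den_g > 0, num_g / np.where(den_g > 0, den_g, 1.0), common)
    raw = np.clip(raw, 0.0, None)
    w = df / (df + prior_replicates)
    per_feature = pd.Series(w * raw + (1 - w) * common, index=cm.features).clip(lower=0.0)
    return DispersionEstimate(common, per_feature, df)


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log PMF of NB with mean ``mean`` and variance ``mean + phi mean^2``."""
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi == 0:
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = 1.0 / phi
    logp = np.log(r) - np.log(r + mean)
    logq = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1.0) + r * logp + k * logq


def _exact_pvalue(s_a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for the split (s_a, t - s_a).

    Group sums of ``n`` i.i.d. NB(mean m, phi) variables are NB with mean
    ``n m`` and dispersion ``phi / n``.  Conditioning on ``t``, p is the
    summed probability of all splits at most as probable as the observed
    one.  ``phi = 0`` gives the conditional binomial distribution with
    success probability ``n_a / (n_a + n_b)``.
    """
    if t == 0:
        return 1.0
    m = t / (n_a + n_b)
    s = np.arange(t + 1)
    logp = _nb_logpmf(s, n_a * m, phi / n_a) + _nb_logpmf(t - s, n_b * m, phi / n_b)
    logp -= np.logaddexp.reduce(logp)
    obs = logp[s_a]
    p = float(np.exp(np.logaddexp.reduce(logp[logp <= obs + 1e-10])))
    return min(1.0, p)


def nb_exact_test(
    cm: CountMatrix,
    factors: NormalizationFactors,
    dispersion: float | pd.Series,
    contrast: tuple[str, str],
) -> pd.Series:
    """Exact NB p-values for a two-condition contrast.

    Counts are scaled to the reference effective library size, summed
    within each group, rounded, and tested conditionally on the total.
    Features with zero total get p = 1.
    """
    cond_a, cond_b = contrast
    cols_a = cm.samples_for(cond_a)
    cols_b = cm.samples_for(cond_b)
    eff = factors.effective_sizes()
    target = factors.reference_effective_size()
    scaled = cm.counts / eff * target
    s_a = np.rint(scaled[cols_a].sum(axis=1).to_numpy()).astype(np.int64)
    s_b = np.rint(scaled[cols_b].sum(axis=1).to_numpy()).astype(np.int64)
    if np.isscalar(dispersion):
        phis = np.full(len(cm.features), float(dispersion))
    else:
        phis = pd.Series(dispersion).reindex(cm.features).to_numpy(dtype=float)
        if np.isnan(phis).any():
            raise DataError("per-feature dispersions missing for some features")
    if (phis < 0).any():
        raise DataError("dispersion must be >= 0")
    pvals = np.ones(len(cm.features))
    for i, (a, b, phi) in enumerate(zip(s_a, s_b, phis)):
        pvals[i] = _exact_pvalue(int(a), int(a + b), len(cols_a), len(cols_b), float(phi))
    return pd.Series(pvals, index=cm.features, name="pvalue")


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, ties stable)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return pvalues
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="qvalue")
    return q


def fold_change(
    cm: CountMatrix,
    factors: NormalizationFactors,
    contrast: tuple[str, str],
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.Series:
    """log2 fold change of normalized group means (A over B).

    ``prior_count`` (default 0.5) is added to each normalized group mean
    so features with an empty group keep a finite estimate.
    """
    cond_a, cond_b = contrast
    norm, _ = _normalized(cm, factors)
    mean_a = norm[cm.samples_for(cond_a)].mean(axis=1)
    mean_b = norm[cm.samples_for(cond_b)].mean(axis=1)
    return pd.Series(
        np.log2((mean_a + prior_count) / (mean_b + prior_count)),
        index=cm.features,
        name="log2fc",
    )


@dataclass
class DEResult:
    """Per-feature statistics for one pairwise contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # columns: log2fc, pvalue, qvalue, direction
    alpha: float = DEFAULT_ALPHA
    dispersion_common: float = 0.0
    factors: NormalizationFactors | None = field(default=None, repr=False)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["qvalue"] < self.alpha]

    def directions(self) -> pd.Series:
        """+1/-1 per significant feature (for overlap/pattern analyses)."""
        sig = self.significant()
        return pd.Series(np.where(sig["log2fc"] >= 0, 1, -1), index=sig.index, dtype=int)


def de_test(
    cm: CountMatrix,
    contrast: tuple[str, str],
    alpha: float = DEFAULT_ALPHA,
    factors: NormalizationFactors | None = None,
    dispersion: float | pd.Series | None = None,
    prior_replicates: float = DEFAULT_PRIOR_REPLICATES,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> DEResult:
    """Full two-group differential-expression analysis for one contrast.

    Computes TMM factors and shrunk per-feature dispersions when not
    supplied, runs the exact NB test, applies BH FDR at ``alpha``, and
    annotates each feature's direction (``up`` means higher in the first
    condition of the contrast; ``ns`` iff q >= alpha).
    """
    factors = factors or tmm_factors(cm)
    disp_common = float("nan")
    if dispersion is None:
        est = estimate_dispersion(cm, factors, prior_replicates)
        # Test with the shrunk per-feature dispersions floored at the common
        # value: with few residual df, downward deviations of the moment
        # estimate are mostly noise and would make the test anti-conservative
        # for exactly the features most likely to be selected.
        dispersion = est.per_feature.clip(lower=est.common)
        disp_common = est.common
    elif np.isscalar(dispersion):
        disp_common = float(dispersion)
    p = nb_exact_test(cm, factors, dispersion, contrast)
    q = bh_fdr(p)
    lfc = fold_change(cm, factors, contrast, prior_count)
    direction = np.where(q >= alpha, NS, np.where(lfc >= 0, UP, DOWN))
    table = pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "qvalue": q, "direction": direction}, index=cm.features
    )
    return DEResult(contrast, table, alpha, disp_common, factors)


def fraction_high_fold(de: DEResult, threshold_fold: float = 4.0) -> float | None:
    """Fraction of significant features with |fold change| at or above a threshold.

    Returns ``None`` when no feature is significant (flagged null rather
    than a division by zero).
    """
    if threshold_fold <= 0:
        raise DataError("threshold_fold must be > 0")
    sig = de.significant()
    if len(sig) == 0:
        return None
    return float((sig["log2fc"].abs() >= np.log2(threshold_fold)).mean())
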