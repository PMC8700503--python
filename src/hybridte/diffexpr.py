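"""Negative-binomial differential expression between two sample groups.

A compact reimplementation of the standard bulk count-based DE workflow:
median-of-ratios library-size normalization, per-family method-of-moments
dispersion estimation shrunk toward a mean-dispersion trend, a two-group
negative-binomial GLM Wald test, Benjamini-Hochberg FDR adjustment, and the
study's DE-calling rule (padj < 0.01 and |log2FC| >= 1). A chi-square
goodness-of-fit test for directional bias of DE calls (over- vs
under-expression against a 50:50 expectation) is included.

The NB model is parameterized as Var = mu + alpha * mu^2; the two-group GLM
decomposes into independent per-group mean fits, solved by a vectorized
Newton iteration on the log-mean scale, with the Wald standard error from
the Fisher information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BiasTestResult",
    "size_factors_median_of_ratios",
    "estimate_dispersion",
    "wald_test",
    "adjust_bh",
    "call_de",
    "de_contrast",
    "bias_test",
]

_MIN_DISP = 1e-8


@dataclass(frozen=True)
class BiasTestResult:
    """1-df chi-square goodness of fit of over vs under DE counts vs 50:50."""

    n_over: int
    n_under: int
    chi2: float
    pvalue: float


def _as_frame(counts) -> pd.DataFrame:
    # accept FamilyCountMatrix or a plain DataFrame
    return counts.counts if hasattr(counts, "counts") else counts


def size_factors_median_of_ratios(counts, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    For each family with all-positive counts, the ratio of each sample's
    count to the family's geometric mean over samples is taken; a sample's
    factor is the median of its ratios. Identical columns get equal factors.

    If no family is positive in every sample, raises ``ValueError`` unless
    ``pseudo_reference=True``, in which case the geometric mean is computed
    on counts + 0.5 over all families instead.
    """
    df = _as_frame(counts)
    mat = df.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logmat = np.log(mat[positive])
        log_geo = logmat.mean(axis=1, keepdims=True)
        log_ratios = logmat - log_geo
    elif pseudo_reference:
        logmat = np.log(mat + 0.5)
        log_geo = logmat.mean(axis=1, keepdims=True)
        log_ratios = logmat - log_geo
    else:
        raise ValueError(
            "no family has positive counts in every sample; "
            "pass pseudo_reference=True to normalize against a pseudo-reference"
        )
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def estimate_dispersion(
    counts,
    size_factors: pd.Series,
    groups: pd.Series | dict | None = None,
    raw_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-family NB dispersion: within-group method of moments + trend shrink.

    Raw estimate per family pools within-group sample means/variances of the
    normalized counts:

        alpha_raw = max(0, sum_g (n_g - 1)(var_g - mean_g)) / sum_g (n_g - 1) mean_g^2)

    A mean-dispersion trend ``alpha(mu) = a0 + a1/mu`` is fit by least
    squares on the positive raw estimates, and the final estimate is a
    log-scale weighted average of raw and trend (weight *raw_weight* on the
    raw side), with raw estimates below the trend floored at the trend —
    at 2-3 replicates the moment estimator lands at 0 for a large share of
    genuinely overdispersed families, and those zeros carry no information.

    Requires >= 2 samples in every group. Returns a DataFrame with columns
    ``mean``, ``raw``, ``trend``, ``alpha``.
    """
    df = _as_frame(counts)
    norm = df.to_numpy(dtype=float) / size_factors.reindex(df.columns).to_numpy()
    if groups is None:
        group_labels = pd.Series("all", index=df.columns)
    else:
        group_labels = pd.Series(groups).reindex(df.columns)

    num = np.zeros(df.shape[0])
    den = np.zeros(df.shape[0])
    overall_mean = norm.mean(axis=1)
    for g in group_labels.unique():
        cols = np.flatnonzero((group_labels == g).to_numpy())
        n_g = len(cols)
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} replicate(s); >= 2 required for dispersion")
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n_g - 1) * (v - m)
        den += (n_g - 1) * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, np.maximum(0.0, num) / np.where(den > 0, den, 1.0), 0.0)

    # trend alpha(mu) = a0 + a1/mu, least squares on families with signal
    usable = (overall_mean > 0) & (raw > _MIN_DISP)
    if usable.sum() >= 3:
        X = np.column_stack([np.ones(usable.sum()), 1.0 / overall_mean[usable]])
        coef, *_ = np.linalg.lstsq(X, raw[usable], rcond=None)
        with np.errstate(divide="ignore"):
            trend = coef[0] + coef[1] / np.where(overall_mean > 0, overall_mean, np.inf)
        trend = np.maximum(trend, _MIN_DISP)
    else:
        trend = np.full(df.shape[0], max(float(raw.mean()), _MIN_DISP))

    floored = np.maximum(raw, trend)
    alpha = np.exp(raw_weight * np.log(np.maximum(floored, _MIN_DISP)) + (1 - raw_weight) * np.log(trend))
    return pd.DataFrame(
        {"mean": overall_mean, "raw": raw, "trend": trend, "alpha": alpha},
        index=df.index,
    )


def _nb_group_fit(counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray, tol: float = 1e-10):
    """Vectorized per-family NB mean MLE for one group.

    counts: (F, n); sf: (n,); alpha: (F,). Returns (beta, info): the
    log-mean-per-unit-size-factor estimate and its Fisher information.
    """
    total = counts.sum(axis=1)
    beta = np.log(np.maximum(total, 1e-12) / sf.sum())
    info = np.full_like(beta, np.nan)
    for _ in range(100):
        mu = sf[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((counts - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-300), -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = sf[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def wald_test(
    counts_a,
    counts_b,
    size_factors: pd.Series,
    dispersion: pd.Series | pd.DataFrame,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB GLM Wald test per family.

    *counts_a*, *counts_b*: families x samples DataFrames for the two
    conditions; log2fc is condition B over A. A small *prior_count* is added
    to every count before fitting to stabilize fold changes of low-count
    families (set to 0 for the unpenalized fit). Families with zero raw
    counts in both groups are reported not testable (NaN statistics).

    Returns a DataFrame with ``baseMean``, ``log2fc``, ``se``, ``pvalue``.
    """
    a = _as_frame(counts_a)
    b = _as_frame(counts_b)
    if not a.index.equals(b.index):
        raise ValueError("count frames must share the same family index")
    alpha = (dispersion["alpha"] if isinstance(dispersion, pd.DataFrame) else dispersion)
    alpha = alpha.reindex(a.index).to_numpy(dtype=float)
    sf_a = size_factors.reindex(a.columns).to_numpy(dtype=float)
    sf_b = size_factors.reindex(b.columns).to_numpy(dtype=float)
    raw_a = a.to_numpy(dtype=float)
    raw_b = b.to_numpy(dtype=float)
    testable = (raw_a.sum(axis=1) + raw_b.sum(axis=1)) > 0

    ka = raw_a + prior_count
    kb = raw_b + prior_count
    beta_a, info_a = _nb_group_fit(ka, sf_a, alpha)
    beta_b, info_b = _nb_group_fit(kb, sf_b, alpha)

    log2 = np.log(2.0)
    lfc = (beta_b - beta_a) / log2
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-300) + 1.0 / np.maximum(info_b, 1e-300)) / log2
    z = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = np.concatenate([raw_a / sf_a, raw_b / sf_b], axis=1).mean(axis=1)

    out = pd.DataFrame(
        {"baseMean": base_mean, "log2fc": lfc, "se": se, "pvalue": pvalue},
        index=a.index,
    )
    out.loc[~testable, ["log2fc", "se", "pvalue"]] = np.nan
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def call_de(results: pd.DataFrame, alpha: float = 0.01, lfc_min: float = 1.0) -> pd.DataFrame:
    """Apply the DE-calling rule: padj < alpha and |log2fc| >= lfc_min.

    Adds ``padj`` (if absent) and ``status`` in {over, under, not_de}
    (not-testable families are not_de). The fold-change boundary is
    inclusive; the padj boundary is strict.
    """
    out = results.copy()
    if "padj" not in out.columns:
        out["padj"] = adjust_bh(out["pvalue"].to_numpy())
    sig = (out["padj"] < alpha) & out["padj"].notna()
    status = np.where(
        sig & (out["log2fc"] >= lfc_min),
        "over",
        np.where(sig & (out["log2fc"] <= -lfc_min), "under", "not_de"),
    )
    out["status"] = status
    return out


def de_contrast(
    counts,
    samples_a: list[str],
    samples_b: list[str],
    alpha: float = 0.01,
    lfc_min: float = 1.0,
    prior_count: float = 0.5,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Full two-group contrast: normalize, estimate dispersion, test, call.

    log2fc is B over A. Size factors default to median-of-ratios on the two
    groups' columns; pass *size_factors* to normalize against a larger
    matrix.
    """
    df = _as_frame(counts)
    sub = df[list(samples_a) + list(samples_b)]
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(sub)
    groups = pd.Series(
        ["A"] * len(samples_a) + ["B"] * len(samples_b), index=list(samples_a) + list(samples_b)
    )
    disp = estimate_dispersion(sub, size_factors, groups)
    res = wald_test(df[list(samples_a)], df[list(samples_b)], size_factors, disp, prior_count)
    return call_de(res, alpha=alpha, lfc_min=lfc_min)


def bias_test(n_over: int, n_under: int) -> BiasTestResult:
    """Directional bias of DE calls: chi-square GOF against 50:50.

    chi2 = (n_over - n_under)^2 / (n_over + n_under), 1 df, upper tail.
    """
    if n_over < 0 or n_under < 0:
        raise ValueError("counts must be non-negative")
    total = n_over + n_under
    if total == 0:
        raise ValueError("at least one DE call required for the bias test")
    chi2 = (n_over - n_under) ** 2 / total
    pvalue = float(stats.chi2.sf(chi2, df=1))
    return BiasTestResult(n_over=n_over, n_under=n_under, chi2=float(chi2), pvalue=pvalue)
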