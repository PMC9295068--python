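"""Normalization and per-sgRNA negative-binomial differential abundance.

The count model follows the DESeq2 lineage: median-of-ratios size factors,
per-guide NB dispersion with a mean–dispersion trend and shrinkage toward
it, and a two-group NB GLM (log link) Wald test.  The GLM is fit by a
per-group Newton iteration on the log-mean, vectorized across all guides
at once, which is exact for a two-group design and fast enough for
genome-scale libraries.

Dispersion shrinkage here is a fixed-weight blend of the per-guide
method-of-moments estimate and the fitted trend — a deliberate
simplification of the full empirical-Bayes MAP machinery; what is promised
(and tested) is parameter recovery and null calibration, not bit-equality
with any external tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .countmatrix import CountMatrix

P_FLOOR = 1e-300
PSEUDOCOUNT = 0.5


def estimate_size_factors(
    counts: CountMatrix | pd.DataFrame, method: str = "median_of_ratios"
) -> pd.Series:
    """Per-sample depth-scaling factors, rescaled to geometric mean 1.

    ``median_of_ratios``: each sample's factor is the median over guides of
    its count divided by that guide's geometric mean across samples; guides
    with a zero in any sample are excluded from the median.  A
    ``total_count`` alternative (library-size ratio) is kept for
    comparison, and ``auto`` falls back to it (with a warning) when no
    guide is nonzero everywhere — as happens after severe bottlenecks.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    if method == "auto":
        try:
            return estimate_size_factors(df, method="median_of_ratios")
        except ValueError:
            warnings.warn(
                "no guide nonzero in every sample; falling back to "
                "total-count size factors",
                stacklevel=2,
            )
            return estimate_size_factors(df, method="total_count")
    if method == "total_count":
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        factors = totals
    elif method == "median_of_ratios":
        allpos = (arr > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no guide has nonzero counts in every sample; median-of-ratios "
                "is undefined (consider method='total_count')"
            )
        sub = arr[allpos]
        geomean = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
        factors = np.median(sub / geomean, axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series
) -> pd.DataFrame:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    return df / size_factors.reindex(df.columns).to_numpy()


@dataclass
class DispersionModel:
    """Raw, trend and final (shrunk) NB dispersions per guide."""

    alpha_raw: pd.Series
    alpha_trend: pd.Series
    alpha_final: pd.Series
    trend_coef: tuple[float, float]  # (a1, a0) in alpha(mu) = a1/mu + a0


def _fit_trend(mu: np.ndarray, alpha_unclipped: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a1/mu + a0 to bin-averaged moment estimates.

    Per-guide moment estimates of alpha are extremely noisy at few
    replicates and clipping them at zero before averaging would bias the
    trend downward, so guides are binned by log mean and the *unclipped*
    estimates averaged within bins before a weighted least-squares fit;
    coefficients are clipped to be non-negative afterwards.
    """
    ok = mu > 0
    if ok.sum() < 10:
        a = alpha_unclipped[ok]
        return 0.0, float(np.clip(np.mean(a), 0.0, None)) if a.size else 0.0
    lmu = np.log(mu[ok])
    a = alpha_unclipped[ok]
    n_bins = min(20, max(3, ok.sum() // 50))
    edges = np.quantile(lmu, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges, lmu, side="right") - 1, 0, n_bins - 1)
    bin_mu, bin_alpha, bin_w = [], [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() < 3:
            continue
        bin_mu.append(np.exp(lmu[sel].mean()))
        bin_alpha.append(a[sel].mean())
        bin_w.append(sel.sum())
    if len(bin_mu) < 2:
        return 0.0, float(np.clip(np.mean(a), 0.0, None))
    X = np.column_stack([1.0 / np.array(bin_mu), np.ones(len(bin_mu))])
    w = np.sqrt(np.array(bin_w, dtype=float))
    coef, *_ = np.linalg.lstsq(X * w[:, None], np.array(bin_alpha) * w, rcond=None)
    return max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)


PRIOR_DF = 16.0


def estimate_dispersions(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    design: pd.Series,
    shrink_weight: float | None = None,
) -> DispersionModel:
    """Method-of-moments dispersion per guide, a fitted mean–dispersion
    trend, and a weighted blend of the two.

    Raw: alpha = max(0, (s^2 - mu) / mu^2) on normalized counts, with the
    within-group pooled variance so a real group effect does not inflate
    dispersion.  The default blend weight on the raw estimate is
    ``dof / (dof + 16)`` (dof = residual degrees of freedom), squeezing
    the very noisy per-guide estimates of small designs toward the trend;
    pass an explicit ``shrink_weight`` in [0, 1] to override.  With no
    residual degrees of freedom the model falls back to the trend alone
    (logged warning).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    y = normalized_counts(df, size_factors).to_numpy(dtype=float)
    design = design.reindex(df.columns)
    groups = [np.flatnonzero((design == g).to_numpy()) for g in design.unique()]
    n = y.shape[1]
    dof = n - len(groups)

    mu = y.mean(axis=1)
    if shrink_weight is None:
        shrink_weight = dof / (dof + PRIOR_DF) if dof > 0 else 0.0
    if dof <= 0:
        warnings.warn(
            "no residual degrees of freedom; using trend-only dispersions",
            stacklevel=2,
        )
        alpha_unclipped = np.zeros_like(mu)
        alpha_raw = np.zeros_like(mu)
        shrink_weight = 0.0
    else:
        ss = np.zeros_like(mu)
        for idx in groups:
            gm = y[:, idx].mean(axis=1, keepdims=True)
            ss += ((y[:, idx] - gm) ** 2).sum(axis=1)
        s2 = ss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_unclipped = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
        alpha_raw = np.clip(alpha_unclipped, 0.0, None)

    a1, a0 = _fit_trend(mu, alpha_unclipped)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(mu > 0, a1 / mu + a0, a0)
    alpha_trend = np.clip(alpha_trend, 1e-8, None)
    alpha_final = shrink_weight * alpha_raw + (1.0 - shrink_weight) * alpha_trend
    idx = df.index
    return DispersionModel(
        pd.Series(alpha_raw, index=idx, name="alpha_raw"),
        pd.Series(alpha_trend, index=idx, name="alpha_trend"),
        pd.Series(np.clip(alpha_final, 0.0, None), index=idx, name="alpha_final"),
        (a1, a0),
    )


def _fit_group_log_mean(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NB GLM fit of one group's mean, guides x samples.

    Solves the log-link score equation sum_s (k - s*m)/(1 + alpha*s*m) = 0
    for m = exp(b) by Newton iteration in b, and returns (m, var(b)) with
    var(b) = 1 / sum_s mu/(1 + alpha*mu) from the Fisher information.
    All-zero groups are clipped at half a normalized count so the Wald
    contrast stays finite.
    """
    k = np.asarray(k, dtype=float)
    s = np.asarray(s, dtype=float)[None, :]
    alpha = np.asarray(alpha, dtype=float)[:, None]
    m_min = PSEUDOCOUNT / s.mean()
    m = np.maximum(k.sum(axis=1) / s.sum(), m_min)[:, None]
    b = np.log(m)
    for _ in range(n_iter):
        mu = s * np.exp(b)
        w = 1.0 + alpha * mu
        score = ((k - mu) / w).sum(axis=1, keepdims=True)
        # d(score)/db, negative definite
        dscore = (-mu * (1.0 + alpha * k) / w**2).sum(axis=1, keepdims=True)
        step = np.clip(score / np.where(dscore == 0, -1.0, dscore), -2.0, 2.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-12:
            break
    m = np.maximum(np.exp(b[:, 0]), m_min)
    mu = s * m[:, None]
    info = (mu / (1.0 + alpha * mu)).sum(axis=1)
    var_b = 1.0 / np.maximum(info, 1e-12)
    return m, var_b


def nb_wald_test(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    dispersions: DispersionModel | pd.Series,
    design: pd.Series,
    treated: str,
    control: str,
) -> pd.DataFrame:
    """Per-guide two-group NB Wald test (treated vs control).

    Returns a DataFrame indexed by sgrna_id with base_mean, log2fc (group
    mean ratio of normalized counts with a 0.5 pseudo-count), p_value
    (two-sided normal reference on the Wald statistic, floored at 1e-300),
    treated_raw_count (max raw count among treated samples) and an
    ``all_zero`` flag; all-zero guides report log2fc 0, p 1.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    design = design.reindex(df.columns)
    for grp in (treated, control):
        if not (design == grp).any():
            raise ValueError(f"design has no sample in group {grp!r}")
    alpha = (
        dispersions.alpha_final
        if isinstance(dispersions, DispersionModel)
        else dispersions
    ).reindex(df.index).to_numpy(dtype=float)

    arr = df.to_numpy(dtype=float)
    sf = size_factors.reindex(df.columns).to_numpy(dtype=float)
    it = np.flatnonzero((design == treated).to_numpy())
    ic = np.flatnonzero((design == control).to_numpy())

    m_t, var_t = _fit_group_log_mean(arr[:, it], sf[it], alpha)
    m_c, var_c = _fit_group_log_mean(arr[:, ic], sf[ic], alpha)

    norm = arr / sf[None, :]
    mean_t = norm[:, it].mean(axis=1)
    mean_c = norm[:, ic].mean(axis=1)
    log2fc = np.log2((mean_t + PSEUDOCOUNT) / (mean_c + PSEUDOCOUNT))

    wald = (np.log(m_t) - np.log(m_c)) / np.sqrt(var_t + var_c)
    p = np.clip(2.0 * stats.norm.sf(np.abs(wald)), P_FLOOR, 1.0)

    all_zero = arr[:, np.concatenate([it, ic])].sum(axis=1) == 0
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0

    out = pd.DataFrame(
        {
            "base_mean": norm[:, np.concatenate([it, ic])].mean(axis=1),
            "log2fc": log2fc,
            "wald_stat": np.where(all_zero, 0.0, wald),
            "p_value": p,
            "treated_raw_count": arr[:, it].max(axis=1).astype(np.int64),
            "treated_norm_count": mean_t,
            "all_zero": all_zero,
        },
        index=df.index,
    )
    out.index.name = "sgrna_id"
    return out


def guide_stats(
    cm: CountMatrix,
    treated: str,
    control: str,
    shrink_weight: float | None = None,
    sf_method: str = "median_of_ratios",
) -> pd.DataFrame:
    """Convenience chain: size factors -> dispersions -> Wald test, using
    only the samples of the two conditions."""
    samples = cm.samples_for(treated) + cm.samples_for(control)
    if not cm.samples_for(treated) or not cm.samples_for(control):
        raise ValueError(f"missing samples for comparison {treated} vs {control}")
    sub = cm.subset_samples(samples)
    design = sub.sample_meta["condition"]
    sf = estimate_size_factors(sub, method=sf_method)
    disp = estimate_dispersions(sub, sf, design, shrink_weight=shrink_weight)
    return nb_wald_test(sub, sf, disp, design, treated, control)
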