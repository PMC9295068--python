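"""Screen-level quality control: sample correlation, library
representation, and distribution comparison.

The standard QC surface for a pooled screen: pairwise Pearson correlation
of log-normalized counts (replicates should correlate tightly; severe
bottlenecks show up as outlier samples), per-sample unique-guide counts
and count quartiles (library representation), and pairwise two-sample
Kolmogorov–Smirnov tests of the count distributions.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .countmatrix import CountMatrix
from .diffabund import estimate_size_factors, normalized_counts


def pearson_matrix(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2(normalized count + 1).

    A zero-variance sample has no defined correlation; its off-diagonal
    entries are NaN with a warning.  ``log_transform=False`` correlates
    the linear normalized counts instead.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if size_factors is None:
        size_factors = estimate_size_factors(df, method="auto")
    y = normalized_counts(df, size_factors).to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    sd = y.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance sample(s) {list(df.columns[degenerate])}: "
            "correlation undefined, reported as NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=df.columns, columns=df.columns)


def unique_sgrnas(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Number of guides with raw count > 0 in each sample."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    return (df > 0).sum(axis=0).rename("unique_sgrnas")


def count_summaries(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Per-sample quartiles (and mean) of normalized counts, the numbers
    behind a representation boxplot."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if size_factors is None:
        size_factors = estimate_size_factors(df, method="auto")
    y = normalized_counts(df, size_factors)
    q = y.quantile([0.0, 0.25, 0.5, 0.75, 1.0]).T
    q.columns = ["min", "q1", "median", "q3", "max"]
    q["mean"] = y.mean(axis=0)
    return q


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def cumulative_distribution(
    counts: CountMatrix | pd.DataFrame, sample: str
) -> pd.DataFrame:
    """ECDF of one sample's guide counts: sorted unique count values with
    cumulative probability, ending at 1."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    col = df[sample].to_numpy(dtype=float)
    if col.size == 0:
        raise ValueError("empty sample")
    values, cnt = np.unique(col, return_counts=True)
    cum = np.cumsum(cnt) / col.size
    return pd.DataFrame({"count": values, "cumulative_probability": cum})


def qc_report(cm: CountMatrix, size_factors: pd.Series | None = None) -> dict:
    """Assemble the full QC report (JSON-serializable)."""
    if size_factors is None:
        size_factors = estimate_size_factors(cm, method="auto")
    pearson = pearson_matrix(cm, size_factors)
    ks = {}
    samples = cm.sample_ids
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            d, p = ks_two_sample(cm.counts[a], cm.counts[b])
            ks[f"{a}|{b}"] = {"D": d, "p_value": p}
    return {
        "samples": samples,
        "size_factors": size_factors.round(6).to_dict(),
        "pearson": pearson.round(6).to_dict(),
        "unique_sgrnas": unique_sgrnas(cm).to_dict(),
        "count_summaries": count_summaries(cm, size_factors).round(4).to_dict("index"),
        "ks_results": ks,
    }


def write_qc_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def plot_qc(cm: CountMatrix, out_dir: str | Path) -> list[Path]:
    """Optional QC figures (correlation heatmap, count boxplots, ECDF
    overlay); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sf = estimate_size_factors(cm)
    made = []

    fig, ax = plt.subplots(figsize=(6, 5))
    r = pearson_matrix(cm, sf)
    im = ax.imshow(r.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(r)), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(r)), r.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    p = out / "qc_pearson.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    y = np.log2(normalized_counts(cm, sf) + 1.0)
    ax.boxplot([y[c] for c in y.columns], labels=y.columns, showfliers=False)
    ax.set_ylabel("log2(normalized count + 1)")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    p = out / "qc_boxplot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in cm.sample_ids:
        ecdf = cumulative_distribution(cm, c)
        ax.step(
            np.log10(ecdf["count"] + 1.0),
            ecdf["cumulative_probability"],
            where="post",
            label=c,
            lw=1,
        )
    ax.set_xlabel("log10(count + 1)")
    ax.set_ylabel("cumulative probability")
    ax.legend(fontsize=6)
    fig.tight_layout()
    p = out / "qc_ecdf.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)
    return made
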