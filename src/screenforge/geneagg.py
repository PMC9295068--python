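"""Gene-level aggregation of per-sgRNA statistics.

Guides are collapsed to their targets (genes and miRNAs; non-targeting
controls are excluded) by taking the mean log2 fold change and combining
the member guides' p-values with Fisher's method, followed by
Benjamini–Hochberg correction across targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import P_FLOOR
from .library import SgRNALibrary


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: X2 = -2 sum ln p_i ~ chi-square with 2k df.

    Inputs are clipped to [1e-300, 1]; with a single p the combined
    p-value equals it exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    p = np.clip(p, P_FLOOR, 1.0)
    x2 = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(x2, df=2 * p.size))
    return x2, max(combined, P_FLOOR)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1; ties resolved by a
    stable sort so equal p-values get equal q-values.
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def aggregate_genes(
    guide_stats: pd.DataFrame,
    library: SgRNALibrary,
    one_sided: bool = False,
    linear_mean_fc: bool = False,
) -> pd.DataFrame:
    """One row per target with >= 1 tested guide.

    ``one_sided=True`` converts the two-sided Wald p-values to
    enrichment-only p-values (p/2 on the enriched side, 1 - p/2 on the
    depleted side) before combining — the recommended setting for a
    positive-selection resistance screen.  ``linear_mean_fc`` reports the
    log2 of the mean linear fold change instead of the mean log2fc.
    Targets whose guides were all zero in every sample are dropped from
    the BH family.
    """
    annot = library.guide_target_frame()
    missing = guide_stats.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"guide(s) without library target: {list(missing[:5])}")
    df = guide_stats.join(annot)
    df = df[df["target_class"] != "non_targeting"]
    if "all_zero" in df.columns:
        tested = df.groupby("target_id")["all_zero"].transform(lambda s: ~s.all())
        df = df[tested]

    p = df["p_value"].to_numpy(dtype=float)
    if one_sided:
        stat = df["wald_stat"].to_numpy(dtype=float)
        p = np.where(stat > 0, p / 2.0, 1.0 - p / 2.0)
        p = np.clip(p, P_FLOOR, 1.0)
    df = df.assign(_p=p)

    rows = []
    for target, grp in df.groupby("target_id", sort=True):
        x2, combined = fisher_combine(grp["_p"].to_numpy())
        if linear_mean_fc:
            mean_lfc = float(np.log2(np.mean(2.0 ** grp["log2fc"].to_numpy())))
        else:
            mean_lfc = float(grp["log2fc"].mean())
        rows.append(
            {
                "target_id": target,
                "target_class": grp["target_class"].iloc[0],
                "n_guides": len(grp),
                "mean_log2fc": mean_lfc,
                "fisher_x2": x2,
                "df": 2 * len(grp),
                "combined_p": combined,
            }
        )
    out = pd.DataFrame(rows).set_index("target_id")
    out["q_value"] = bh_adjust(out["combined_p"].to_numpy()) if len(out) else []
    return out
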