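"""Hit identification: thresholds, top-N ranking, core intersection, trend.

A resistance hit must both be well-represented (raw/normalized count above
a floor) and strongly enriched (log2 fold change above a cutoff); the
"core" genes are targets whose guides rank in the top-N enriched sets of
every screened condition, and the "trend group" holds guides whose counts
increase strictly along the in-vivo progression
lenvatinib_cell < primary_tumor < lung_metastasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .countmatrix import CountMatrix
from .diffabund import estimate_size_factors, normalized_counts
from .library import SgRNALibrary

DEFAULT_TOP_N = {"lenvatinib_cell": 600, "primary_tumor": 400, "lung_metastasis": 200}


@dataclass
class HitCallConfig:
    """Thresholds (strict ``>``) and per-comparison top-N sizes."""

    min_count: float = 100.0
    min_log2fc: float = 3.0
    top_n: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TOP_N))
    rank_key: str = "log2fc"
    count_column: str = "treated_norm_count"  # or "treated_raw_count"

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_log2fc < 0:
            raise ValueError("thresholds must be >= 0")
        if any(n <= 0 for n in self.top_n.values()):
            raise ValueError("top_n values must be positive")


def threshold_hits(stats: pd.DataFrame, cfg: HitCallConfig) -> list[str]:
    """Guides with count > min_count AND log2fc > min_log2fc (both strict)."""
    keep = (stats[cfg.count_column] > cfg.min_count) & (
        stats["log2fc"] > cfg.min_log2fc
    )
    return list(stats.index[keep])


def top_n_guides(stats: pd.DataFrame, n: int, rank_key: str = "log2fc") -> list[str]:
    """First n guides by rank_key descending; ties broken by smaller
    p-value, then lexicographic guide id.  Asking for more guides than
    exist returns them all."""
    work = stats.assign(_id=stats.index.astype(str))
    ordered = work.sort_values(
        [rank_key, "p_value", "_id"], ascending=[False, True, True], kind="stable"
    )
    if n > len(ordered):
        import warnings

        warnings.warn(
            f"top_n={n} exceeds {len(ordered)} available guides; returning all",
            stacklevel=2,
        )
        n = len(ordered)
    return list(ordered.index[:n])


def core_intersection(
    top_sets: dict[str, list[str]], library: SgRNALibrary
) -> tuple[set[str], set[str]]:
    """Guides present in every per-comparison set, and their targets."""
    if len(top_sets) < 2:
        raise ValueError("core intersection needs >= 2 comparisons")
    sets = [set(s) for s in top_sets.values()]
    core_guides = set.intersection(*sets)
    core_genes = set(library.targets_of(core_guides).values())
    return core_guides, core_genes


def trend_group(
    cm: CountMatrix,
    normalize: bool = True,
    stages: tuple[str, str, str] = ("lenvatinib_cell", "primary_tumor", "lung_metastasis"),
) -> list[str]:
    """Guides whose replicate-mean counts obey the strict ordering
    lung_metastasis > primary_tumor > lenvatinib_cell.

    Counts are size-factor normalized by default so the ordering is not a
    sequencing-depth artifact; ``normalize=False`` uses raw counts.
    """
    if normalize:
        sf = estimate_size_factors(cm, method="auto")
        counts = normalized_counts(cm, sf)
    else:
        counts = cm.counts.astype(float)
    means = {}
    for stage in stages:
        samples = cm.samples_for(stage)
        if not samples:
            raise ValueError(f"no samples for condition {stage!r}")
        means[stage] = counts[samples].mean(axis=1)
    lenva, primary, met = (means[s] for s in stages)
    keep = (met > primary) & (primary > lenva)
    return list(counts.index[keep])


def hit_report(
    per_comparison_stats: dict[str, pd.DataFrame],
    cm: CountMatrix,
    library: SgRNALibrary,
    cfg: HitCallConfig | None = None,
) -> dict:
    """Full hit-calling pass over the per-comparison guide statistics.

    For each comparison: the threshold-surviving guide set and, among
    guides passing the count filter, the top-N by the ranking key; then
    the core intersection across comparisons and the trend group.
    """
    cfg = cfg or HitCallConfig()
    threshold_sets: dict[str, list[str]] = {}
    top_sets: dict[str, list[str]] = {}
    for comparison, stats in per_comparison_stats.items():
        threshold_sets[comparison] = threshold_hits(stats, cfg)
        passing = stats[stats[cfg.count_column] > cfg.min_count]
        n = cfg.top_n.get(comparison, min(len(passing), 100))
        top_sets[comparison] = top_n_guides(passing, min(n, len(passing)), cfg.rank_key)
    core_guides, core_genes = core_intersection(top_sets, library)
    trend = trend_group(cm)
    return {
        "threshold_hits": threshold_sets,
        "top_n": top_sets,
        "core_guides": sorted(core_guides),
        "core_genes": sorted(core_genes),
        "trend_guides": sorted(trend),
        "config": {
            "min_count": cfg.min_count,
            "min_log2fc": cfg.min_log2fc,
            "top_n": cfg.top_n,
            "rank_key": cfg.rank_key,
            "count_column": cfg.count_column,
        },
    }
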