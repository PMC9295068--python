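"""The sgRNA × sample count matrix and its sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("control_cell", "lenvatinib_cell", "primary_tumor", "lung_metastasis")


@dataclass
class CountMatrix:
    """Integer guide×sample counts plus per-sample condition/replicate labels.

    ``counts`` is a pandas DataFrame (rows: sgrna_id in library order,
    columns: sample_id).  ``sample_meta`` is indexed by sample_id with
    columns ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(
                {"condition": "unknown", "replicate": "R1"},
                index=self.counts.columns,
            )
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        m = self.sample_meta["condition"] == condition
        return list(self.sample_meta.index[m])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[sample_ids].copy(), self.sample_meta.loc[sample_ids].copy()
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "sgrna_id"
        out.to_csv(path, sep="\t")

    def meta_to_tsv(self, path: str | Path) -> None:
        out = self.sample_meta.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, meta_path: str | Path | None = None
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sgrna_id")
        counts = counts.astype(np.int64)
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype=str)
            return cls(counts, meta)
        return cls(counts)


def assemble_count_matrix(
    per_sample_counts: dict[str, pd.Series | dict],
    sample_meta: pd.DataFrame,
    sgrna_ids: list[str],
) -> CountMatrix:
    """Assemble per-sample count vectors into one matrix in library order.

    Every sample must have been quantified against the same library
    (``sgrna_ids``); a sample whose index is not a subset of the library is
    a hard error.  Samples with zero assigned reads yield all-zero columns.
    """
    cols = {}
    for sample_id, c in per_sample_counts.items():
        s = pd.Series(c, dtype=np.int64)
        extra = set(s.index) - set(sgrna_ids)
        if extra:
            raise ValueError(
                f"sample {sample_id!r}: guide(s) not in declared library: "
                f"{sorted(extra)[:5]}"
            )
        cols[sample_id] = s.reindex(sgrna_ids, fill_value=0)
    counts = pd.DataFrame(cols, index=pd.Index(sgrna_ids, name="sgrna_id"))
    counts = counts[list(per_sample_counts)]  # deterministic column order
    return CountMatrix(counts, sample_meta.loc[list(per_sample_counts)].copy())
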