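"""sgRNA library annotations: loading, validation, merging and spacer indexing.

A pooled-screen library is a table of guides, each carrying a fixed-length
nucleotide spacer (the countable barcode), a target (gene symbol, miRNA id,
or a non-targeting control label) and a target class.  The genome-scale
GeCKO-style designs this models are distributed as two half-libraries (A/B)
that are merged before quantification.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

TARGET_CLASSES = ("gene", "miRNA", "non_targeting")
LIBRARY_COLUMNS = ("sgrna_id", "spacer", "target_id", "target_class")

_ACGT = frozenset("ACGT")


class LibraryError(ValueError):
    """Malformed or inconsistent sgRNA library annotation."""


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: unique id, fixed-length ACGT spacer, and its target."""

    sgrna_id: str
    spacer: str
    target_id: str
    target_class: str

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise LibraryError(
                f"sgRNA {self.sgrna_id!r}: target_class {self.target_class!r} "
                f"not in {TARGET_CLASSES}"
            )
        if not set(self.spacer) <= _ACGT:
            bad = sorted(set(self.spacer) - _ACGT)
            raise LibraryError(
                f"sgRNA {self.sgrna_id!r}: spacer contains non-ACGT symbols {bad}"
            )


@dataclass
class SgRNALibrary:
    """Ordered collection of validated guides sharing one spacer length."""

    records: list[SgRNARecord]
    spacer_length: int = 20
    name: str = "library"
    duplicate_spacers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = Counter(r.sgrna_id for r in self.records)
        dup_ids = sorted(i for i, c in ids.items() if c > 1)
        if dup_ids:
            raise LibraryError(f"duplicate sgrna_id(s): {dup_ids[:10]}")
        for r in self.records:
            if len(r.spacer) != self.spacer_length:
                raise LibraryError(
                    f"sgRNA {r.sgrna_id!r}: spacer length {len(r.spacer)} "
                    f"!= declared {self.spacer_length}"
                )
        # duplicate spacers are legal (real half-libraries contain a few)
        # but recorded so downstream matching can treat them as ambiguous
        by_spacer: dict[str, list[str]] = {}
        for r in self.records:
            by_spacer.setdefault(r.spacer, []).append(r.sgrna_id)
        self.duplicate_spacers = {
            s: ids for s, ids in by_spacer.items() if len(ids) > 1
        }

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sgrna_ids(self) -> list[str]:
        return [r.sgrna_id for r in self.records]

    def targets_of(self, sgrna_ids: Iterable[str]) -> dict[str, str]:
        """Map each given guide id to its target_id."""
        lut = {r.sgrna_id: r.target_id for r in self.records}
        missing = [g for g in sgrna_ids if g not in lut]
        if missing:
            raise LibraryError(f"guide(s) not in library: {missing[:10]}")
        return {g: lut[g] for g in sgrna_ids}

    def guide_target_frame(self) -> pd.DataFrame:
        """Guide→target annotation as a DataFrame indexed by sgrna_id."""
        return pd.DataFrame(
            {
                "target_id": [r.target_id for r in self.records],
                "target_class": [r.target_class for r in self.records],
            },
            index=pd.Index(self.sgrna_ids, name="sgrna_id"),
        )

    def validation_report(self) -> dict:
        """Summary counts per target class, plus duplicate-spacer flags."""
        class_counts = Counter(r.target_class for r in self.records)
        target_counts = Counter(
            r.target_id for r in self.records if r.target_class != "non_targeting"
        )
        return {
            "name": self.name,
            "n_sgrnas": len(self.records),
            "spacer_length": self.spacer_length,
            "per_class": {c: class_counts.get(c, 0) for c in TARGET_CLASSES},
            "n_targets": len(target_counts),
            "n_duplicate_spacers": len(self.duplicate_spacers),
            "duplicate_spacers": {
                s: ids for s, ids in list(self.duplicate_spacers.items())[:50]
            },
        }

    def write_validation_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.validation_report(), indent=2))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.sgrna_id, r.spacer, r.target_id, r.target_class) for r in self.records],
            columns=list(LIBRARY_COLUMNS),
        )
        df.to_csv(path, sep="\t", index=False)


def load_library(
    path: str | Path, spacer_length: int = 20, name: str | None = None
) -> SgRNALibrary:
    """Load a 4-column TSV library annotation (header required).

    Columns: sgrna_id, spacer, target_id, target_class.  Spacers are
    case-folded to uppercase.  Duplicate ids, non-ACGT spacers and wrong
    spacer lengths are hard errors naming the offending row; duplicate
    spacers are permitted and flagged in the validation report.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"{path}: missing column(s) {missing}")

    records: list[SgRNARecord] = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        sgrna_id = row.sgrna_id.strip()
        spacer = row.spacer.strip().upper()
        if not sgrna_id:
            raise LibraryError(f"{path}: row {row_no}: empty sgrna_id")
        if sgrna_id in seen:
            raise LibraryError(
                f"{path}: row {row_no}: duplicate sgrna_id {sgrna_id!r} "
                f"(first seen at row {seen[sgrna_id]})"
            )
        seen[sgrna_id] = row_no
        if not set(spacer) <= _ACGT:
            raise LibraryError(
                f"{path}: row {row_no}: sgRNA {sgrna_id!r} spacer contains "
                f"non-ACGT symbols"
            )
        if len(spacer) != spacer_length:
            raise LibraryError(
                f"{path}: row {row_no}: sgRNA {sgrna_id!r} spacer length "
                f"{len(spacer)} != declared {spacer_length}"
            )
        try:
            records.append(
                SgRNARecord(sgrna_id, spacer, row.target_id.strip(), row.target_class.strip())
            )
        except LibraryError as e:
            raise LibraryError(f"{path}: row {row_no}: {e}") from None
    return SgRNALibrary(records, spacer_length=spacer_length, name=name or path.stem)


def merge_libraries(a: SgRNALibrary, b: SgRNALibrary, name: str = "merged") -> SgRNALibrary:
    """Disjoint union of two half-libraries sharing a spacer length.

    The merged size equals ``len(a) + len(b)``; any sgrna_id present in both
    halves is a hard error listing the collisions.
    """
    if a.spacer_length != b.spacer_length:
        raise LibraryError(
            f"spacer length mismatch: {a.spacer_length} vs {b.spacer_length}"
        )
    collisions = sorted(set(a.sgrna_ids) & set(b.sgrna_ids))
    if collisions:
        raise LibraryError(
            f"{len(collisions)} sgrna_id collision(s) between libraries: "
            f"{collisions[:10]}"
        )
    return SgRNALibrary(
        list(a.records) + list(b.records), spacer_length=a.spacer_length, name=name
    )


def build_spacer_index(lib: SgRNALibrary) -> Mapping[str, frozenset[str]]:
    """Exact-lookup index spacer → set of sgrna_ids.

    Spacers carried by more than one guide map to multi-id sets; reads
    hitting them are counted as ambiguous downstream.
    """
    index: dict[str, set[str]] = {}
    for r in lib.records:
        index.setdefault(r.spacer, set()).add(r.sgrna_id)
    return {s: frozenset(ids) for s, ids in index.items()}
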