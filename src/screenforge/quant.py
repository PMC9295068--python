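"""Spacer extraction from FASTQ reads and per-sample guide counting.

Pooled-screen quantification is effectively exact-match lookup of the 20-nt
spacer window against the library, so this module replaces an external
aligner with hash matching: exact first, then (optionally) all
single-substitution neighbours of the extracted window.  Reads matching more
than one guide are ambiguous and excluded from counts, mirroring the
multi-mapping discard behaviour of alignment-based pipelines.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class QuantConfig:
    """How to locate and match the spacer within each read.

    Either a fixed 0-based ``spacer_offset``, or ``anchored=True`` with a
    5' and/or 3' constant flank sequence bounding the spacer.
    ``max_mismatch`` is 0 (exact) or 1 (single substitution).
    """

    spacer_length: int = 20
    spacer_offset: int = 0
    anchored: bool = False
    flank5: str = ""
    flank3: str = ""
    max_mismatch: int = 1
    min_read_length: int = 20
    try_revcomp: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.anchored and not (self.flank5 or self.flank3):
            raise ValueError("anchored matching needs flank5 and/or flank3")
        self.flank5 = self.flank5.upper()
        self.flank3 = self.flank3.upper()


def extract_spacer(read: str, cfg: QuantConfig) -> str | None:
    """Pull the candidate spacer window out of a read, or None."""
    read = read.upper()
    L = cfg.spacer_length
    if cfg.anchored:
        if cfg.flank5:
            i = read.find(cfg.flank5)
            if i < 0:
                return None
            start = i + len(cfg.flank5)
        else:
            j = read.find(cfg.flank3)
            if j < 0:
                return None
            start = j - L
        if start < 0 or start + L > len(read):
            return None
        window = read[start : start + L]
        if cfg.flank3 and not read[start + L :].startswith(cfg.flank3):
            return None
        return window
    start = cfg.spacer_offset
    if start + L > len(read):
        return None
    return read[start : start + L]


def _mismatch_hits(spacer: str, index: Mapping[str, frozenset[str]]) -> set[str]:
    hits: set[str] = set()
    for i, base in enumerate(spacer):
        prefix, suffix = spacer[:i], spacer[i + 1 :]
        for sub in "ACGT":
            if sub == base:
                continue
            ids = index.get(prefix + sub + suffix)
            if ids:
                hits |= ids
    return hits


def match_read(read: str, index: Mapping[str, frozenset[str]], cfg: QuantConfig) -> str:
    """Assign a read to a guide id, or ``unassigned``/``ambiguous``.

    Exact hash lookup of the extracted window first; if that misses and
    ``max_mismatch == 1``, all single-substitution neighbours are looked up.
    A unique guide hit assigns the read; hits on more than one distinct
    guide (including spacers shared by several guides) are ambiguous.
    """
    if len(read) < cfg.min_read_length:
        return UNASSIGNED
    windows = [extract_spacer(read, cfg)]
    if cfg.try_revcomp:
        windows.append(extract_spacer(_revcomp(read), cfg))
    hits: set[str] = set()
    exact = False
    for w in windows:
        if w is None:
            continue
        ids = index.get(w)
        if ids:
            hits |= ids
            exact = True
    if not exact and cfg.max_mismatch == 1:
        for w in windows:
            if w is not None:
                hits |= _mismatch_hits(w, index)
    if not hits:
        return UNASSIGNED
    if len(hits) > 1:
        return AMBIGUOUS
    return next(iter(hits))


class FastqFormatError(ValueError):
    """Malformed FASTQ record, reported with its record number."""


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_reads(fastq: str | Path | Iterable[str]) -> Iterator[str]:
    """Yield read sequences from a FASTQ path (gz-transparent) or an
    iterable of raw sequences (handy in tests and simulation)."""
    if isinstance(fastq, (str, Path)):
        with _open_maybe_gz(fastq) as fh:
            record_no = 0
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    record_no += 1
                    yield seq
            except ValueError as e:
                raise FastqFormatError(
                    f"{fastq}: malformed FASTQ at record {record_no + 1}: {e}"
                ) from None
    else:
        yield from fastq


def quantify_sample(
    fastq: str | Path | Iterable[str],
    index: Mapping[str, frozenset[str]],
    cfg: QuantConfig,
) -> tuple[pd.Series, dict[str, int]]:
    """Count guide assignments over a read stream.

    Returns (per-guide counts over every guide in the index, tally dict).
    Conservation holds by construction:
    ``assigned + unassigned + ambiguous == total`` and the per-guide counts
    sum to ``assigned``.
    """
    counts: Counter[str] = Counter()
    tally = {"assigned": 0, UNASSIGNED: 0, AMBIGUOUS: 0, "total": 0}
    for seq in iter_reads(fastq):
        tally["total"] += 1
        hit = match_read(seq, index, cfg)
        if hit == UNASSIGNED:
            tally[UNASSIGNED] += 1
        elif hit == AMBIGUOUS:
            tally[AMBIGUOUS] += 1
        else:
            tally["assigned"] += 1
            counts[hit] += 1
    all_ids = sorted(set().union(*index.values())) if index else []
    series = pd.Series(
        [counts.get(g, 0) for g in all_ids], index=all_ids, dtype="int64"
    )
    return series, tally


def write_fastq(path: str | Path, reads: Iterable[str], prefix: str = "read") -> int:
    """Write plain-text FASTQ with uniform quality; returns read count."""
    n = 0
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
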