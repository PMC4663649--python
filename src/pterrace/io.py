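"""Readers for alignments and partition schemes; coverage extraction.

A supermatrix plus a RAxML-style partition definition yields the
taxa x partitions coverage matrix: a taxon is *present* in a partition iff
its block contains at least one character outside the missing alphabet
(``? - N n X x .`` by default).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import AlignIO, SeqIO

from .terrace import CoverageMatrix
from .treecore import TaxonIndex

__all__ = [
    "Alignment",
    "PartitionScheme",
    "read_alignment",
    "read_partitions",
    "parse_partition_text",
    "extract_coverage",
    "DEFAULT_MISSING_CHARS",
]

DEFAULT_MISSING_CHARS = frozenset("?-NnXx.")


@dataclass(frozen=True)
class Alignment:
    """Aligned sequences, in file order."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate sequence names: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged sequence lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PartitionScheme:
    """Named partitions as lists of 1-based inclusive column intervals."""

    names: tuple[str, ...]
    ranges: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self):
        if len(self.names) != len(self.ranges):
            raise ValueError("names/ranges length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate partition names")
        seen: list[tuple[int, int, str]] = []
        for name, intervals in zip(self.names, self.ranges):
            for start, end in intervals:
                if start < 1 or end < start:
                    raise ValueError(
                        f"invalid interval {start}-{end} in partition {name!r}"
                    )
                seen.append((start, end, name))
        seen.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(seen, seen[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping intervals: {s1}-{e1} ({n1!r}) and "
                    f"{s2}-{e2} ({n2!r})"
                )

    def __len__(self) -> int:
        return len(self.names)

    def columns(self, j: int) -> np.ndarray:
        """0-based column indices of partition ``j``."""
        cols: list[int] = []
        for start, end in self.ranges[j]:
            cols.extend(range(start - 1, end))
        return np.asarray(cols, dtype=int)

    def max_column(self) -> int:
        return max(end for intervals in self.ranges for _s, end in intervals)


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            return "fasta" if line.lstrip().startswith(">") else "phylip"
    raise ValueError("empty alignment file")


def read_alignment(path, format: str = "auto") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment."""
    text = Path(path).read_text()
    if format == "auto":
        format = _sniff_format(text)
    if format == "fasta":
        records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return Alignment(
            tuple(r.id for r in records), tuple(str(r.seq) for r in records)
        )
    if format == "phylip":
        aln = AlignIO.read(_io.StringIO(text), "phylip-relaxed")
        return Alignment(
            tuple(r.id for r in aln), tuple(str(r.seq) for r in aln)
        )
    raise ValueError(f"unknown alignment format: {format!r}")


_PARTITION_LINE = re.compile(
    r"^\s*(?P<type>[A-Za-z][A-Za-z0-9+]*)\s*,\s*(?P<name>[^=\s]+)\s*=\s*(?P<ranges>.+?)\s*$"
)
_RANGE = re.compile(r"^(?P<start>\d+)\s*-\s*(?P<end>\d+)$")


def parse_partition_text(text: str) -> PartitionScheme:
    """Parse RAxML-style partition lines: ``DNA, name = 1-500, 700-900``.

    Codon-interleaved syntax (``1-100\\3``) is rejected explicitly rather
    than misparsed.
    """
    names: list[str] = []
    ranges: list[tuple[tuple[int, int], ...]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _PARTITION_LINE.match(line)
        if not m:
            raise ValueError(f"malformed partition line {lineno}: {raw!r}")
        intervals = []
        for chunk in m.group("ranges").split(","):
            chunk = chunk.strip()
            if "\\" in chunk or "/" in chunk:
                raise ValueError(
                    f"codon-interleaved range {chunk!r} on line {lineno} is "
                    "not supported"
                )
            rm = _RANGE.match(chunk)
            if not rm:
                raise ValueError(f"malformed range {chunk!r} on line {lineno}")
            intervals.append((int(rm.group("start")), int(rm.group("end"))))
        names.append(m.group("name"))
        ranges.append(tuple(intervals))
    if not names:
        raise ValueError("no partitions defined")
    return PartitionScheme(tuple(names), tuple(ranges))


def read_partitions(path) -> PartitionScheme:
    return parse_partition_text(Path(path).read_text())


def extract_coverage(
    alignment: Alignment,
    scheme: PartitionScheme,
    missing_chars: Iterable[str] = DEFAULT_MISSING_CHARS,
    min_sites: int = 1,
    taxa: TaxonIndex | None = None,
) -> CoverageMatrix:
    """Presence/absence of each taxon in each partition block.

    A taxon is present iff its block holds at least ``min_sites``
    characters outside ``missing_chars``.
    """
    if scheme.max_column() > alignment.length:
        raise ValueError(
            f"partition scheme extends to column {scheme.max_column()} but "
            f"the alignment has only {alignment.length}"
        )
    if min_sites < 1:
        raise ValueError("min_sites must be at least 1")
    missing = frozenset(missing_chars)
    if taxa is None:
        taxa = TaxonIndex(alignment.names)
    chars = np.array([list(s) for s in alignment.sequences])
    non_missing = ~np.isin(chars, list(missing))
    order = [alignment.names.index(name) for name in taxa.names]
    present = np.zeros((len(taxa), len(scheme)), dtype=bool)
    for j in range(len(scheme)):
        cols = scheme.columns(j)
        counts = non_missing[:, cols].sum(axis=1)
        present[:, j] = counts[order] >= min_sites
    return CoverageMatrix(taxa, scheme.names, present)
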