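"""FASTA/FASTQ reading, writing and mate pairing.

Every other module consumes only :class:`SequenceRecord`, so all format
handling is confined here.  FASTQ qualities are Phred+33 (the encoding
emitted by SRA fastq-dump); bases are uppercased on input and restricted
to {A, C, G, T, N}.  Coordinates everywhere in the toolkit are 0-based,
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, PairingError, ParseError

_VALID_BASES = frozenset("ACGTN")
_MATE_SUFFIX = re.compile(r"[/._][12]$")


@dataclass
class SequenceRecord:
    """One read or clone: id, bases, optional Phred qualities, source label."""

    id: str
    bases: str
    quals: tuple[int, ...] | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid base(s) {sorted(bad)!r}; "
                "only A, C, G, T, N are accepted"
            )
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise FormatError(
                f"record {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadPair:
    """A forward/reverse mate pair; the reverse mate is stored as given."""

    fwd: SequenceRecord
    rev: SequenceRecord

    @property
    def id(self) -> str:
        return strip_mate_suffix(self.fwd.id)


def strip_mate_suffix(read_id: str) -> str:
    """Remove a trailing /1, /2 (or ._-style) mate suffix from an id."""
    return _MATE_SUFFIX.sub("", read_id)


def _parse_fasta(lines: list[str]) -> list[tuple[str, str, int]]:
    records: list[tuple[str, str, int]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks), header_line))
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise ParseError("empty FASTA header", lineno)
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise ParseError("sequence data before first '>' header", lineno)
            chunks.append(line.strip())
    if header is not None:
        records.append((header, "".join(chunks), header_line))
    return records


def _parse_fastq(lines: list[str]) -> list[tuple[str, str, str, int]]:
    records: list[tuple[str, str, str, int]] = []
    # drop a single trailing newline-only tail
    while lines and lines[-1].strip() == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"FASTQ line count {len(lines)} is not a multiple of 4",
            len(lines),
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = (lines[i + j].rstrip("\n") for j in range(4))
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError("expected '@' FASTQ header", lineno)
        if not plus.startswith("+"):
            raise ParseError("expected '+' separator", lineno + 2)
        name = head[1:].split()[0] if head[1:].split() else ""
        if not name:
            raise ParseError("empty FASTQ header", lineno)
        if len(seq) != len(qual):
            raise FormatError(
                f"record {name!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)} (line {lineno + 3})"
            )
        records.append((name, seq, qual, lineno))
    return records


def read_sequences(path: str | Path, format: str | None = None) -> list[SequenceRecord]:
    """Read an ordered collection of records from a FASTA or FASTQ file.

    ``format`` is 'fasta' or 'fastq'; when omitted it is inferred from the
    file suffix.  Bases are uppercased; FASTQ qualities decoded as Phred+33.
    Ids must be unique within a file.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {format!r}")
    lines = path.read_text().splitlines(keepends=True)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    if format == "fasta":
        for name, seq, lineno in _parse_fasta(lines):
            if name in seen:
                raise ParseError(f"duplicate id {name!r}", lineno)
            seen.add(name)
            records.append(SequenceRecord(id=name, bases=seq.upper()))
    else:
        for name, seq, qual, lineno in _parse_fastq(lines):
            if name in seen:
                raise ParseError(f"duplicate id {name!r}", lineno)
            seen.add(name)
            quals = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 for q in quals):
                raise FormatError(
                    f"record {name!r}: quality character below '!' "
                    f"(line {lineno + 3}); Phred+33 expected"
                )
            records.append(SequenceRecord(id=name, bases=seq.upper(), quals=quals))
    return records


def write_sequences(
    records: Iterable[SequenceRecord],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write records as single-line FASTA or canonical 4-line FASTQ."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.bases}\n")
            elif format == "fastq":
                quals = rec.quals
                if quals is None:
                    quals = (30,) * len(rec.bases)
                qual_str = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual_str}\n")
            else:
                raise ValueError(f"unknown format {format!r}")


def pair_reads(
    fwd: Sequence[SequenceRecord],
    rev: Sequence[SequenceRecord],
) -> list[ReadPair]:
    """Pair forward and reverse mate collections rank by rank.

    Ids must match after stripping a trailing /1, /2 (or ._-separated) mate
    suffix.  The reverse mate is stored as given, not reverse-complemented.
    """
    if len(fwd) != len(rev):
        raise PairingError(
            f"mate collections differ in size: {len(fwd)} vs {len(rev)}"
        )
    pairs: list[ReadPair] = []
    for rank, (f, r) in enumerate(zip(fwd, rev)):
        if strip_mate_suffix(f.id) != strip_mate_suffix(r.id):
            raise PairingError(
                f"mate ids disagree: {f.id!r} vs {r.id!r}", rank=rank
            )
        pairs.append(ReadPair(fwd=f, rev=r))
    return pairs
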