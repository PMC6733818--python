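"""Repeat-content screening of merged reads against a satellite library.

Replaces a general repeat-masking engine with direct local alignment of
each library monomer (both strands) to the read.  Qualifying alignments
(identity >= ``min_local_identity`` over the local alignment, length >= 25
columns) contribute masked intervals; the union of intervals over repeated
rounds of masking gives the read's repeat fraction.  Reads are retained
when the repeat fraction reaches the threshold (0.99 by default, focusing
the downstream clustering on tandemly arrayed sequence), and a 25-bp
sliding window over alignment start coordinates locates the densest
read-start anchor region on a reference monomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._align import LocalHit, local_align, local_score, revcomp
from .errors import SatconnectError
from .merge import MergedRead
from .seqio import SequenceRecord

DEFAULT_MIN_LOCAL_IDENTITY = 0.7
MIN_ALIGNMENT_COLUMNS = 25
DEFAULT_RETENTION_THRESHOLD = 0.99
DEFAULT_ANCHOR_WINDOW = 25


@dataclass
class MaskAnnotation:
    """Per-read repeat intervals (0-based half-open, disjoint) and fraction."""

    read_id: str
    intervals: list[tuple[int, int]]
    best_hit: str | None
    repeat_fraction: float


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def mask_read(
    read: SequenceRecord | MergedRead,
    library: Sequence[SequenceRecord],
    min_local_identity: float = DEFAULT_MIN_LOCAL_IDENTITY,
) -> MaskAnnotation:
    """Annotate repeat content of one read against the satellite library.

    Iterative best-hit masking: the highest-scoring local alignment over
    all library monomers and strands is taken; if it qualifies its read
    interval is hard-masked and the search repeats, so a read spanning a
    monomer junction (two partial copies) is fully covered.  ``best_hit``
    is the library id of the first (highest-scoring) qualifying alignment.
    """
    if not read.bases:
        raise SatconnectError("empty read")
    if not library:
        raise SatconnectError("empty satellite library")

    variants: list[tuple[str, str]] = []
    for monomer in library:
        variants.append((monomer.id, monomer.bases))
        variants.append((monomer.id, revcomp(monomer.bases)))

    work = read.bases
    intervals: list[tuple[int, int]] = []
    best_hit: str | None = None
    while True:
        best: tuple[float, int] | None = None  # (score, variant index)
        for idx, (_, seq) in enumerate(variants):
            score = local_score(work, seq, masked=True)
            if best is None or score > best[0]:
                best = (score, idx)
        if best is None or best[0] <= 0:
            break
        hit = local_align(work, variants[best[1]][1], masked=True)
        if hit.columns < MIN_ALIGNMENT_COLUMNS or hit.identity < min_local_identity:
            break
        s, e = hit.query_interval
        if best_hit is None:
            best_hit = variants[best[1]][0]
        intervals.append((s, e))
        work = work[:s] + "x" * (e - s) + work[e:]
        if _union_length(_merge_intervals(intervals)) == len(read.bases):
            break

    intervals = _merge_intervals(intervals)
    fraction = _union_length(intervals) / len(read.bases)
    return MaskAnnotation(
        read_id=read.id,
        intervals=intervals,
        best_hit=best_hit,
        repeat_fraction=fraction,
    )


@dataclass
class ScreenStats:
    """Filtering statistics; best-hit tallies feed cluster normalisation."""

    initial: int = 0
    retained: int = 0
    best_hit_tally: dict[str, int] = field(default_factory=dict)
    annotations: list[MaskAnnotation] = field(default_factory=list)


def filter_reads(
    reads: Sequence[MergedRead | SequenceRecord],
    library: Sequence[SequenceRecord],
    threshold: float = DEFAULT_RETENTION_THRESHOLD,
    min_local_identity: float = DEFAULT_MIN_LOCAL_IDENTITY,
) -> tuple[list[MergedRead | SequenceRecord], ScreenStats]:
    """Retain reads whose repeat fraction reaches ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    stats = ScreenStats(initial=len(reads))
    retained: list[MergedRead | SequenceRecord] = []
    for read in reads:
        ann = mask_read(read, library, min_local_identity)
        stats.annotations.append(ann)
        if ann.repeat_fraction >= threshold:
            retained.append(read)
            stats.retained += 1
            if ann.best_hit is not None:
                stats.best_hit_tally[ann.best_hit] = (
                    stats.best_hit_tally.get(ann.best_hit, 0) + 1
                )
    return retained, stats


def read_start_coordinate(
    read: SequenceRecord | MergedRead, reference: SequenceRecord
) -> int | None:
    """Leftmost reference coordinate of the read's best local alignment.

    Strand-symmetric: reverse-strand hits also report the leftmost forward
    coordinate on the reference.  None when the read does not align.
    """
    fwd = local_align(read.bases, reference.bases)
    rev = local_align(revcomp(read.bases), reference.bases)
    hit = rev if rev.score > fwd.score else fwd
    if hit.score <= 0:
        return None
    return hit.target_interval[0]


def anchor_window(
    reads: Sequence[SequenceRecord | MergedRead],
    reference: SequenceRecord,
    window: int = DEFAULT_ANCHOR_WINDOW,
) -> tuple[int, int]:
    """Half-open reference window containing the most read-start coordinates.

    Exhaustive scan over every window start; ties break toward the smallest
    start coordinate.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(reference.bases) < window:
        raise ValueError("reference shorter than window")
    starts = [
        s for s in (read_start_coordinate(r, reference) for r in reads)
        if s is not None
    ]
    if not starts:
        raise SatconnectError("no anchors: no read aligns to the reference")
    counts = np.bincount(starts, minlength=len(reference.bases))
    n_windows = len(reference.bases) - window + 1
    sums = np.convolve(counts, np.ones(window, dtype=int), mode="valid")[:n_windows]
    s = int(np.argmax(sums))  # argmax returns the first (smallest) index
    return (s, s + window)
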