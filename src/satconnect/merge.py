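"""Overlap-based merging of paired-end reads into single fragments.

Each pair is merged by reverse-complementing the reverse mate and scanning
every candidate 3' overlap length ``k`` (``min_overlap <= k <= min(len f,
len r)``): the last ``k`` bases of the forward read are compared, ungapped,
with the first ``k`` bases of the reverse-complemented mate.  Overlaps are
scored as matches - mismatches; the best-scoring overlap whose mismatch
rate is within ``max_mismatch_rate`` wins, ties going to the longer
overlap.  Within the overlap the base with the higher quality is emitted
(forward base on quality ties).  No merge is a normal outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._align import revcomp
from .seqio import ReadPair, SequenceRecord

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATE = 0.1


@dataclass(frozen=True)
class MergedRead:
    """A merged fragment with provenance of the chosen overlap."""

    id: str
    bases: str
    quals: tuple[int, ...]
    overlap_len: int
    mismatches_in_overlap: int
    source: str | None = None

    def __len__(self) -> int:
        return len(self.bases)

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.id, bases=self.bases, quals=self.quals, source=self.source
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> MergedRead | None:
    """Merge one pair, or return None when no overlap qualifies."""
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    if not (0 <= max_mismatch_rate < 0.5):
        raise ValueError("max_mismatch_rate must be in [0, 0.5)")

    fwd = pair.fwd
    rev_bases = revcomp(pair.rev.bases)
    rev_quals = pair.rev.quals
    if rev_quals is not None:
        rev_quals = rev_quals[::-1]

    f_arr = _encode(fwd.bases)
    r_arr = _encode(rev_bases)
    max_k = min(len(f_arr), len(r_arr))

    best_k = 0
    best_score = None
    best_mm = 0
    for k in range(min_overlap, max_k + 1):
        mism = int(np.count_nonzero(f_arr[len(f_arr) - k:] != r_arr[:k]))
        if mism / k > max_mismatch_rate:
            continue
        score = (k - mism) - mism
        # ties broken toward the longer overlap (>= with ascending k)
        if best_score is None or score >= best_score:
            best_score = score
            best_k = k
            best_mm = mism
    if best_score is None:
        return None

    k = best_k
    f_quals = fwd.quals if fwd.quals is not None else (30,) * len(fwd.bases)
    r_quals = rev_quals if rev_quals is not None else (30,) * len(rev_bases)

    head = fwd.bases[: len(fwd.bases) - k]
    head_q = f_quals[: len(fwd.bases) - k]
    tail = rev_bases[k:]
    tail_q = r_quals[k:]

    overlap_bases = []
    overlap_quals = []
    for i in range(k):
        fb = fwd.bases[len(fwd.bases) - k + i]
        fq = f_quals[len(fwd.bases) - k + i]
        rb = rev_bases[i]
        rq = r_quals[i]
        if rq > fq:
            overlap_bases.append(rb)
            overlap_quals.append(rq)
        else:  # tie -> forward base
            overlap_bases.append(fb)
            overlap_quals.append(fq)

    bases = head + "".join(overlap_bases) + tail
    quals = tuple(head_q) + tuple(overlap_quals) + tuple(tail_q)
    return MergedRead(
        id=pair.id,
        bases=bases,
        quals=quals,
        overlap_len=k,
        mismatches_in_overlap=best_mm,
        source=fwd.source,
    )


@dataclass
class MergeStats:
    """Run statistics for a merge pass."""

    total_pairs: int = 0
    merged: int = 0

    @property
    def unmerged(self) -> int:
        return self.total_pairs - self.merged


def merge_pairs(
    pairs: Iterable[ReadPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[list[MergedRead], MergeStats]:
    """Merge a collection of pairs, collecting run statistics."""
    stats = MergeStats()
    merged: list[MergedRead] = []
    for pair in pairs:
        stats.total_pairs += 1
        result = merge_pair(pair, min_overlap, max_mismatch_rate)
        if result is not None:
            stats.merged += 1
            merged.append(result)
    return merged, stats
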