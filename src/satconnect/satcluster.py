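"""Greedy incremental identity clustering of satellite reads.

The clustering heart of the pipeline: reads are sorted by length
(descending, ties by id), the first read founds cluster 0, and every
subsequent read joins the best existing representative whose identity
reaches the threshold (95/97/99% in the study design), else founds a new
cluster.  Identity is matches / length of the shorter sequence under a
free-terminal-gap global alignment maximised over strands — the convention
of greedy clusterers like cd-hit-est, where a read must be covered along
its full length to join a cluster.  A length-ratio cutoff (0.8) restricts
which representatives a read may join.

Cluster summaries carry per-source composition (the originating sequencing
library of each member), raw and normalised counts, and Shannon's H over
the composition (natural log).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._align import global_identity
from .errors import SatconnectError
from .merge import MergedRead
from .seqio import SequenceRecord

DEFAULT_LENGTH_DIFF_CUTOFF = 0.8
CLUSTER_THRESHOLDS = (0.95, 0.97, 0.99)


def pairwise_identity(
    a: SequenceRecord | MergedRead, b: SequenceRecord | MergedRead
) -> float:
    """Identity fraction between two sequences, maximised over strands.

    Global alignment with free terminal gaps (match +1, mismatch -1, gap
    open -2, gap extension -1); identity = matched columns / length of the
    shorter sequence.
    """
    if not a.bases or not b.bases:
        raise SatconnectError("empty sequence")
    return global_identity(a.bases, b.bases, both_strands=True)


@dataclass
class Cluster:
    """One cluster: members, representative, composition and statistics."""

    id: int
    representative: SequenceRecord | MergedRead
    members: list[str] = field(default_factory=list)
    composition: dict[str, int] = field(default_factory=dict)
    norm_initial: float | None = None
    norm_filtered: float | None = None
    shannon_h: float | None = None

    @property
    def raw_count(self) -> int:
        return len(self.members)

    @property
    def n_sources(self) -> int:
        return len(self.composition)


def cluster_greedy(
    seqs: Sequence[SequenceRecord | MergedRead],
    threshold: float,
    length_diff_cutoff: float = DEFAULT_LENGTH_DIFF_CUTOFF,
    assignment: str = "best",
) -> list[Cluster]:
    """Greedy incremental clustering at the given identity threshold.

    ``assignment='best'`` joins the qualifying representative of highest
    identity; ``'first'`` joins the first qualifying one in cluster order.
    The resulting partition is exhaustive and disjoint.
    """
    if not seqs:
        raise SatconnectError("no sequences to cluster")
    if assignment not in {"best", "first"}:
        raise ValueError("assignment must be 'best' or 'first'")

    ordered = sorted(seqs, key=lambda r: (-len(r.bases), r.id))
    clusters: list[Cluster] = []
    for seq in ordered:
        chosen: Cluster | None = None
        best_identity = 0.0
        for cluster in clusters:
            rep = cluster.representative
            ratio = min(len(seq.bases), len(rep.bases)) / max(
                len(seq.bases), len(rep.bases)
            )
            if ratio < length_diff_cutoff:
                continue
            identity = pairwise_identity(seq, rep)
            if identity >= threshold:
                if assignment == "first":
                    chosen = cluster
                    break
                if identity > best_identity:
                    best_identity = identity
                    chosen = cluster
        if chosen is None:
            clusters.append(Cluster(id=len(clusters), representative=seq,
                                    members=[seq.id]))
        else:
            chosen.members.append(seq.id)
    return clusters


def shannon_h(composition: Mapping[str, int]) -> float:
    """Shannon's H (natural log) of a source-composition mapping."""
    total = sum(composition.values())
    if total == 0:
        return 0.0
    h = 0.0
    for count in composition.values():
        if count > 0:
            p = count / total
            h -= p * math.log(p)
    return h


def summarize_cluster(
    cluster: Cluster,
    source_of: Mapping[str, str],
    initial_totals: Mapping[str, int],
    filtered_totals: Mapping[str, int],
) -> Cluster:
    """Fill composition, normalised counts and Shannon's H in place.

    ``initial_totals`` and ``filtered_totals`` map source label to the
    number of reads entering the pipeline and the number passing the repeat
    filter; the two normalisations divide the raw count by the respective
    totals summed over the sources present in the mapping.
    """
    composition: dict[str, int] = {}
    for member in cluster.members:
        if member not in source_of:
            raise SatconnectError(f"no source label for read {member!r}")
        label = source_of[member]
        composition[label] = composition.get(label, 0) + 1
    cluster.composition = composition
    initial_sum = sum(initial_totals.values())
    filtered_sum = sum(filtered_totals.values())
    cluster.norm_initial = cluster.raw_count / initial_sum if initial_sum else None
    cluster.norm_filtered = cluster.raw_count / filtered_sum if filtered_sum else None
    cluster.shannon_h = shannon_h(composition)
    return cluster


def summarize_clusters(
    clusters: Sequence[Cluster],
    source_of: Mapping[str, str],
    initial_totals: Mapping[str, int],
    filtered_totals: Mapping[str, int],
) -> list[Cluster]:
    return [
        summarize_cluster(c, source_of, initial_totals, filtered_totals)
        for c in clusters
    ]
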