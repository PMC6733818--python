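"""Satellite monomer statistics: consensus, identity matrices, CENP-B scan,
and in-silico restriction digestion of tandem arrays.

Consensus monomers are built by a center-star progressive multiple
alignment (the clone with the highest mean pairwise identity to the others
anchors the alignment; every other clone is aligned to it and merged under
the once-a-gap-always-a-gap rule).  Intraspecific identity is the mean of
all unordered clone-pair identities within a species; interspecific
identity compares species consensuses, with IUPAC ambiguity codes counting
as a match whenever they contain the other base.  A species pair is
flagged for limited concerted evolution when its interspecific identity
exceeds the intraspecific identity of one of the species.

The CENP-B box scan scores every 17-bp window of a consensus (both
strands) by how many of the nine binding-critical positions it conserves.
The digest model cuts a tandem array at every exact restriction-site
occurrence and bins fragment lengths into the monomer-periodic ladder that
a Southern blot of a homogeneous array produces.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._align import (
    IUPAC_CODES,
    _GLOBAL,
    bases_match,
    global_identity,
    revcomp,
)
from .errors import SatconnectError
from .seqio import SequenceRecord


@dataclass
class ConsensusMonomer:
    """Species consensus: bases (possibly IUPAC codes) and clone depth."""

    species: str
    bases: str
    depth: int


@dataclass
class IdentityMatrix:
    """Square percent-identity matrix over ordered labels."""

    labels: list[str]
    values: np.ndarray  # percent, symmetric, diagonal 100

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass(frozen=True)
class MotifHit:
    """Best placement of the CENP-B box on a consensus monomer."""

    offset: int              # window start on the forward consensus
    strand: str              # '+' or '-'
    critical_matches: int    # 0..9
    matched_positions: tuple[int, ...]  # motif indices of conserved criticals
    total_matches: int
    window: str


@dataclass(frozen=True)
class CenpBMotif:
    """A motif consensus plus the indices of its binding-critical positions."""

    sequence: str
    critical_positions: tuple[int, ...]


#: Human 17-bp CENP-B box consensus with its nine binding-critical
#: positions (0-based).  Configuration data: pass a different motif to
#: scan_cenpb to scan for another binding box.
CENPB_BOX = CenpBMotif(
    sequence="YTTCGTTGGAARCGGGA",
    critical_positions=(1, 2, 3, 4, 9, 12, 13, 14, 15),
)


@dataclass
class DigestProfile:
    """Fragment multiset of a complete digest, with monomer-ladder binning."""

    fragment_lengths: list[int]
    monomer_length: int

    def ladder(self) -> dict[int, int]:
        """Rung -> fragment count, rung k = fragments of ~k monomers."""
        rungs: Counter[int] = Counter()
        for length in self.fragment_lengths:
            rungs[round(length / self.monomer_length)] += 1
        return dict(sorted(rungs.items()))


# ---------------------------------------------------------------------------
# consensus construction


def _orient(seq: str, center: str) -> str:
    """Flip ``seq`` to the strand with higher identity to ``center``."""
    fwd = global_identity(center, seq, both_strands=False)
    rev = global_identity(center, revcomp(seq), both_strands=False)
    return revcomp(seq) if rev > fwd else seq


def _star_msa(center: str, others: Sequence[str]) -> list[str]:
    """Center-star MSA rows (center first) under once-a-gap-always-a-gap."""
    L = len(center)
    # per-sequence pairwise alignment to the center, as gapped string pairs
    pairs: list[tuple[str, str]] = []
    for seq in others:
        alignment = _GLOBAL.align(center, seq)[0]
        pairs.append((str(alignment[0]), str(alignment[1])))
    # insertions[i]: columns inserted before center position i (i == L: after end)
    max_ins = [0] * (L + 1)
    parsed = []
    for gc, gs in pairs:
        cols: list[list[str]] = [[] for _ in range(L + 1)]  # insertion chars
        at: list[str] = []  # character aligned to each center position
        pos = 0
        for a, b in zip(gc, gs):
            if a == "-":
                cols[pos].append(b)
            else:
                at.append(b)
                pos += 1
        parsed.append((cols, at))
        for i in range(L + 1):
            max_ins[i] = max(max_ins[i], len(cols[i]))
    rows: list[str] = []
    center_row = []
    for i in range(L):
        center_row.append("-" * max_ins[i] + center[i])
    center_row.append("-" * max_ins[L])
    rows.append("".join(center_row))
    for cols, at in parsed:
        row = []
        for i in range(L):
            ins = "".join(cols[i])
            row.append(ins.rjust(max_ins[i], "-") + at[i])
        row.append("".join(cols[L]).ljust(max_ins[L], "-"))
        rows.append("".join(row))
    return rows


def build_consensus(
    clones: Sequence[SequenceRecord], species: str = ""
) -> ConsensusMonomer:
    """Majority-rule consensus of >= 2 clones via center-star alignment.

    Per column: majority base; ties become the IUPAC code of the tied set;
    columns with more than 50% gaps are dropped.
    """
    if len(clones) < 2:
        raise SatconnectError("need at least 2 clones for a consensus")
    seqs = [c.bases for c in clones]
    # center: highest mean pairwise identity to the rest
    n = len(seqs)
    mean_identity = []
    for i in range(n):
        total = sum(
            global_identity(seqs[i], seqs[j]) for j in range(n) if j != i
        )
        mean_identity.append(total / (n - 1))
    center_idx = max(range(n), key=lambda i: (mean_identity[i], -i))
    center = seqs[center_idx]
    others = [
        _orient(seqs[i], center) for i in range(n) if i != center_idx
    ]
    rows = _star_msa(center, others)
    n_rows = len(rows)
    consensus: list[str] = []
    for col in zip(*rows):
        gaps = col.count("-")
        if gaps > n_rows / 2:
            continue
        counts = Counter(c for c in col if c not in "-N")
        if not counts:
            continue
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top)
        if len(tied) == 1:
            consensus.append(next(iter(tied)))
        else:
            consensus.append(IUPAC_CODES.get(tied, "N"))
    return ConsensusMonomer(species=species, bases="".join(consensus), depth=n)


# ---------------------------------------------------------------------------
# identity matrices and the concerted-evolution flag


def intra_identity(clones: Sequence[SequenceRecord]) -> float:
    """Mean pairwise percent identity over all unordered clone pairs."""
    if len(clones) < 2:
        raise SatconnectError("need at least 2 clones")
    total = 0.0
    n_pairs = 0
    for i in range(len(clones)):
        for j in range(i + 1, len(clones)):
            total += global_identity(clones[i].bases, clones[j].bases)
            n_pairs += 1
    return 100.0 * total / n_pairs


def identity_matrix(
    groups: Mapping[str, Sequence[SequenceRecord]],
    mode: str,
    consensuses: Mapping[str, ConsensusMonomer] | None = None,
) -> dict[str, float] | IdentityMatrix:
    """Intra- or inter-specific identity summary.

    ``mode='intra'``: label -> mean pairwise clone identity (percent) within
    each group.  ``mode='inter'``: square matrix of consensus-vs-consensus
    percent identities (ambiguity codes match any base they contain);
    consensuses are built from the groups unless supplied.
    """
    labels = list(groups)
    if mode == "intra":
        return {label: intra_identity(groups[label]) for label in labels}
    if mode != "inter":
        raise ValueError("mode must be 'intra' or 'inter'")
    if consensuses is None:
        consensuses = {
            label: build_consensus(groups[label], species=label)
            for label in labels
        }
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            identity = 100.0 * global_identity(
                consensuses[labels[i]].bases,
                consensuses[labels[j]].bases,
                ambiguity=True,
            )
            values[i, j] = values[j, i] = identity
    return IdentityMatrix(labels=labels, values=values)


def concerted_evolution_test(
    intra: Mapping[str, float], inter: IdentityMatrix
) -> list[tuple[str, str]]:
    """Ordered pairs (i, j) where interspecific identity exceeds intra(i).

    A non-empty result marks species whose satellite is *more* similar to
    another species' than to its own copies — the opposite of what
    homogenising molecular drive predicts.
    """
    if set(intra) != set(inter.labels):
        raise SatconnectError("intra and inter label sets differ")
    flags: list[tuple[str, str]] = []
    for i in inter.labels:
        for j in inter.labels:
            if i != j and inter.get(i, j) > intra[i]:
                flags.append((i, j))
    return flags


# ---------------------------------------------------------------------------
# CENP-B box scan


def scan_cenpb(
    consensus: ConsensusMonomer | SequenceRecord,
    motif: CenpBMotif = CENPB_BOX,
) -> MotifHit:
    """Best placement of the motif over every window of both strands.

    Windows are ranked by conserved critical positions, then total motif
    matches, then smaller offset, then '+' strand.  Offsets refer to the
    forward strand of the consensus.
    """
    seq = consensus.bases
    k = len(motif.sequence)
    if len(seq) < k:
        raise SatconnectError(f"consensus shorter than the {k}-bp motif")
    best: MotifHit | None = None
    for strand in "+-":
        scan_seq = seq if strand == "+" else revcomp(seq)
        for start in range(len(seq) - k + 1):
            window = scan_seq[start : start + k]
            matched = tuple(
                p for p in motif.critical_positions
                if bases_match(window[p], motif.sequence[p])
            )
            total = sum(
                1 for a, b in zip(window, motif.sequence) if bases_match(a, b)
            )
            offset = start if strand == "+" else len(seq) - k - start
            hit = MotifHit(
                offset=offset,
                strand=strand,
                critical_matches=len(matched),
                matched_positions=matched,
                total_matches=total,
                window=window,
            )
            if best is None or _hit_key(hit) < _hit_key(best):
                best = hit
    assert best is not None
    return best


def _hit_key(hit: MotifHit):
    return (-hit.critical_matches, -hit.total_matches, hit.offset,
            0 if hit.strand == "+" else 1)


# ---------------------------------------------------------------------------
# in-silico restriction digestion


def digest_array(
    array: SequenceRecord,
    site: str = "CCGG",
    monomer_length: int = 345,
    cut_offset: int = 1,
) -> DigestProfile:
    """Complete digest of a linear array at every exact site occurrence.

    The fragment boundary falls ``cut_offset`` bases into the site (1 for
    MspI's C^CGG).  Fragment lengths always sum to the array length.
    """
    if not site:
        raise SatconnectError("empty restriction site")
    if not array.bases:
        raise SatconnectError("empty array")
    seq = array.bases
    cuts: list[int] = []
    pos = seq.find(site)
    while pos != -1:
        cuts.append(pos + cut_offset)
        pos = seq.find(site, pos + 1)
    bounds = [0] + cuts + [len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return DigestProfile(fragment_lengths=fragments, monomer_length=monomer_length)
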