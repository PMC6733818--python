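"""Shared pairwise-alignment kernels.

All alignment in the toolkit goes through the two scorers defined here,
both with match +1, mismatch -1, gap open -2, gap extension -1:

* a *global* aligner with free terminal gaps, used for monomer-vs-monomer
  identity (clustering, identity matrices, consensus building);
* a *local* (Smith-Waterman) aligner, used for repeat masking, read
  anchoring and inter-cluster similarity.

Percent identities derived from the global aligner use the length of the
shorter sequence as denominator (the convention of greedy incremental
clusterers such as cd-hit-est, where a short spurious terminal overlap
must not count as high identity).  Local identities are over the columns
of the local alignment itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

#: IUPAC nucleotide ambiguity codes -> set of bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: base set -> IUPAC code (inverse of IUPAC_SETS).
IUPAC_CODES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXTEND = -1


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC codes map to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def bases_match(a: str, b: str) -> bool:
    """True when the IUPAC sets of the two symbols intersect.

    An ambiguity code counts as a match iff it contains the other base;
    plain bases reduce to equality.
    """
    if a == b and a in IUPAC_SETS:
        return True
    sa = IUPAC_SETS.get(a)
    sb = IUPAC_SETS.get(b)
    if sa is None or sb is None:
        return False
    return not sa.isdisjoint(sb)


def _make_global() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.end_gap_score = 0  # free terminal gaps
    return aligner


def _make_local() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@lru_cache(maxsize=1)
def _iupac_matrix():
    """Substitution matrix scoring +1 for intersecting IUPAC sets, -1 else.

    Lowercase 'x' is a hard-mask symbol that never matches anything,
    including itself.
    """
    alphabet = "ACGTRYSWKMBDHVNx"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "x" or b == "x":
                m[a, b] = MISMATCH
            else:
                m[a, b] = MATCH if bases_match(a, b) else MISMATCH
    return m


def _make_global_iupac() -> Align.PairwiseAligner:
    aligner = _make_global()
    aligner.substitution_matrix = _iupac_matrix()
    return aligner


def _make_local_masked() -> Align.PairwiseAligner:
    """Local aligner whose alphabet tolerates IUPAC codes and 'x' masks."""
    aligner = _make_local()
    aligner.substitution_matrix = _iupac_matrix()
    return aligner


_GLOBAL = _make_global()
_LOCAL = _make_local()
_GLOBAL_IUPAC = _make_global_iupac()
_LOCAL_MASKED = _make_local_masked()


def _count_matches(alignment, match_fn: Callable[[str, str], bool]) -> tuple[int, int]:
    """(matching columns, total aligned columns incl. internal gaps).

    Terminal-gap columns of a free-end-gap global alignment are excluded.
    """
    target = alignment.target
    query = alignment.query
    blocks_t, blocks_q = alignment.aligned
    matches = 0
    aligned_cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            # internal gap columns between consecutive aligned blocks
            aligned_cols += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(target[ts:te], query[qs:qe]):
            if match_fn(a, b):
                matches += 1
        aligned_cols += te - ts
        prev_t, prev_q = te, qe
    return matches, aligned_cols


def global_identity(
    a: str,
    b: str,
    *,
    both_strands: bool = True,
    ambiguity: bool = False,
) -> float:
    """Identity fraction between two sequences under free-end-gap alignment.

    Identity = matching columns / length of the shorter sequence, maximised
    over the two strands of ``b`` when ``both_strands`` is set.  With
    ``ambiguity`` set, IUPAC codes match any base they contain.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _GLOBAL_IUPAC if ambiguity else _GLOBAL
    match_fn = bases_match if ambiguity else str.__eq__
    denom = min(len(a), len(b))
    best = 0.0
    candidates = [b, revcomp(b)] if both_strands else [b]
    for cand in candidates:
        alignment = aligner.align(a, cand)[0]
        matches, _ = _count_matches(alignment, match_fn)
        best = max(best, matches / denom)
        if best == 1.0:
            break
    return best


@dataclass(frozen=True)
class LocalHit:
    """One best local alignment of a query against a target."""

    score: float
    identity: float          # matches / alignment columns
    matches: int
    columns: int             # aligned columns incl. internal gaps
    query_interval: tuple[int, int]   # 0-based half-open on the query
    target_interval: tuple[int, int]  # 0-based half-open on the target
    strand: str              # strand of the target variant aligned: '+'/'-'


def local_align(query: str, target: str, *, masked: bool = False) -> LocalHit:
    """Best Smith-Waterman alignment of ``target`` within/against ``query``.

    Single strand; callers handle reverse complements so that reported
    query coordinates stay on the query as given.  ``masked`` selects the
    IUPAC/'x'-aware scorer (the 'x' symbol never matches).
    """
    aligner = _LOCAL_MASKED if masked else _LOCAL
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        return LocalHit(0.0, 0.0, 0, 0, (0, 0), (0, 0), "+")
    alignment = alignments[0]
    match_fn = bases_match if masked else str.__eq__
    matches, columns = _count_matches(alignment, match_fn)
    blocks_t, blocks_q = alignment.aligned
    q_iv = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    t_iv = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    identity = matches / columns if columns else 0.0
    return LocalHit(float(alignment.score), identity, matches, columns, q_iv, t_iv, "+")


def local_best_hit(query: str, target: str, *, masked: bool = False) -> LocalHit:
    """Best local hit over both strands of ``target``.

    Query coordinates always refer to the query as given; for a reverse
    strand hit the target interval refers to the reverse complement of the
    target and ``strand`` is '-'.
    """
    fwd = local_align(query, target, masked=masked)
    rev = local_align(query, revcomp(target), masked=masked)
    if rev.score > fwd.score:
        return LocalHit(rev.score, rev.identity, rev.matches, rev.columns,
                        rev.query_interval, rev.target_interval, "-")
    return fwd


def local_score(query: str, target: str, *, masked: bool = False) -> float:
    """Score-only local alignment (no traceback), single strand."""
    aligner = _LOCAL_MASKED if masked else _LOCAL
    return float(aligner.score(query, target))
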