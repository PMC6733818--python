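"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (plain DP tables, naive
exhaustive scans, Pruefer-sequence enumeration) and never calls the
package's alignment or clustering code paths, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import itertools
from collections import Counter

NEG_INF = float("-inf")

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2   # cost of the first gap position
GAP_EXTEND = -1

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def sw_affine(a: str, b: str) -> tuple[int, int, int]:
    """Smith-Waterman with affine gaps; returns (score, matches, columns).

    Gotoh three-state DP with full traceback; ties prefer diagonal moves.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # a[i-1] vs b[j-1]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = (0.0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
            if M[i][j] > best[0]:
                best = (M[i][j], i, j)
    score, i, j = best
    if score <= 0:
        return (0, 0, 0)
    # traceback from the best cell through whichever state is live
    matches = 0
    columns = 0
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            here = M[i][j]
            if here == 0:
                break
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if a[i - 1] == b[j - 1]:
                matches += 1
            columns += 1
            prev = here - s
            if prev == 0 and M[i - 1][j - 1] <= 0 and X[i - 1][j - 1] < 0 \
                    and Y[i - 1][j - 1] < 0:
                i, j = i - 1, j - 1
                break
            if M[i - 1][j - 1] == prev:
                state = "M"
            elif X[i - 1][j - 1] == prev:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
            if state == "M" and M[i][j] == 0:
                break
        elif state == "X":
            columns += 1
            if X[i - 1][j] + GAP_EXTEND == X[i][j]:
                state = "X"
            else:
                state = "M"
            i -= 1
        else:
            columns += 1
            if Y[i][j - 1] + GAP_EXTEND == Y[i][j]:
                state = "Y"
            else:
                state = "M"
            j -= 1
    return (int(score), matches, columns)


def sw_best_over_strands(a: str, b: str) -> tuple[int, int, int]:
    fwd = sw_affine(a, b)
    rev = sw_affine(a, rc(b))
    return rev if rev[0] > fwd[0] else fwd


def nw_free_end_identity(a: str, b: str) -> float:
    """Free-end-gap global alignment identity = matches / min(len a, len b).

    Maximised over both strands of ``b``.
    """

    def one(a: str, b: str) -> int:
        n, m = len(a), len(b)
        M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
        X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
        Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
        # free terminal gaps: zero-cost leading gaps
        M[0][0] = 0.0
        for i in range(1, n + 1):
            X[i][0] = 0.0
        for j in range(1, m + 1):
            Y[0][j] = 0.0
        TM = [[0] * (m + 1) for _ in range(n + 1)]  # matches along best path
        TX = [[0] * (m + 1) for _ in range(n + 1)]
        TY = [[0] * (m + 1) for _ in range(n + 1)]
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
                opts = (
                    (M[i - 1][j - 1], TM[i - 1][j - 1]),
                    (X[i - 1][j - 1], TX[i - 1][j - 1]),
                    (Y[i - 1][j - 1], TY[i - 1][j - 1]),
                )
                val, mat = max(opts, key=lambda t: (t[0], t[1]))
                M[i][j] = val + s
                TM[i][j] = mat + (1 if a[i - 1] == b[j - 1] else 0)
                # gap consuming a
                xo = (M[i - 1][j] + GAP_OPEN, TM[i - 1][j])
                xe = (X[i - 1][j] + GAP_EXTEND, TX[i - 1][j])
                X[i][j], TX[i][j] = max(xo, xe, key=lambda t: (t[0], t[1]))
                yo = (M[i][j - 1] + GAP_OPEN, TM[i][j - 1])
                ye = (Y[i][j - 1] + GAP_EXTEND, TY[i][j - 1])
                Y[i][j], TY[i][j] = max(yo, ye, key=lambda t: (t[0], t[1]))
                if i == n:  # free trailing gap in a's row: handled below
                    pass
        # free trailing gaps: best over last row/column end states
        best = (NEG_INF, 0)
        for j in range(m + 1):
            for V, T in ((M, TM), (X, TX), (Y, TY)):
                if V[n][j] > NEG_INF:
                    cand = (V[n][j], T[n][j])
                    if cand > best:
                        best = cand
        for i in range(n + 1):
            for V, T in ((M, TM), (X, TX), (Y, TY)):
                if V[i][m] > NEG_INF:
                    cand = (V[i][m], T[i][m])
                    if cand > best:
                        best = cand
        return best[1]

    denom = min(len(a), len(b))
    return max(one(a, b), one(a, rc(b))) / denom


def best_overlap(fwd: str, rev_rc: str, min_overlap: int,
                 max_mismatch_rate: float):
    """Exhaustive 3'-overlap scorer: (overlap_len, mismatches) or None."""
    best = None
    for k in range(min_overlap, min(len(fwd), len(rev_rc)) + 1):
        tail = fwd[len(fwd) - k:]
        head = rev_rc[:k]
        mism = sum(1 for x, y in zip(tail, head) if x != y)
        if mism / k > max_mismatch_rate:
            continue
        score = (k - mism) - mism
        if best is None or score >= best[0]:
            best = (score, k, mism)
    if best is None:
        return None
    return (best[1], best[2])


def greedy_cluster_partition(
    seqs: list[tuple[str, str]],
    identities: dict[tuple[str, str], float],
    threshold: float,
    length_diff_cutoff: float = 0.8,
) -> list[list[str]]:
    """Greedy best-assignment clustering from a precomputed identity matrix.

    ``seqs`` is [(id, bases)]; identities keyed by unordered id pairs.
    """

    def identity(x: str, y: str) -> float:
        return identities[(x, y)] if (x, y) in identities else identities[(y, x)]

    ordered = sorted(seqs, key=lambda r: (-len(r[1]), r[0]))
    lengths = {rid: len(bases) for rid, bases in ordered}
    clusters: list[list[str]] = []
    for rid, bases in ordered:
        best = None
        best_identity = 0.0
        for cluster in clusters:
            rep = cluster[0]
            ratio = min(lengths[rid], lengths[rep]) / max(lengths[rid], lengths[rep])
            if ratio < length_diff_cutoff:
                continue
            ident = identity(rid, rep)
            if ident >= threshold and ident > best_identity:
                best_identity = ident
                best = cluster
        if best is None:
            clusters.append([rid])
        else:
            best.append(rid)
    return clusters


def all_spanning_trees_min_distance(n: int, dist: dict[tuple[int, int], float]):
    """Minimum total distance over all labelled spanning trees (Pruefer)."""

    import bisect

    def tree_from_pruefer(seq: tuple[int, ...]) -> list[tuple[int, int]]:
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        edges = []
        leaves = sorted(v for v in range(n) if degree[v] == 1)
        for x in seq:
            leaf = leaves.pop(0)
            edges.append((min(leaf, x), max(leaf, x)))
            degree[leaf] -= 1
            degree[x] -= 1
            if degree[x] == 1:
                bisect.insort(leaves, x)
        u, v = [v for v in range(n) if degree[v] == 1]
        edges.append((min(u, v), max(u, v)))
        return edges

    best = None
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = tree_from_pruefer(seq)
        total = sum(dist[e] for e in edges)
        if best is None or total < best:
            best = total
    return best


def naive_anchor_window(starts: list[int], ref_len: int, window: int):
    """Exhaustive sliding-window scan; smallest-start tie-break."""
    best_s, best_count = 0, -1
    for s in range(ref_len - window + 1):
        count = sum(1 for x in starts if s <= x < s + window)
        if count > best_count:
            best_s, best_count = s, count
    return (best_s, best_s + window)


def naive_motif_scan(seq: str, motif: str, critical: tuple[int, ...],
                     match_fn) -> tuple[int, str, int]:
    """(critical_matches, strand, offset) of the best window, naive ranking."""
    k = len(motif)
    candidates = []
    for strand, s in (("+", seq), ("-", rc(seq))):
        for start in range(len(seq) - k + 1):
            window = s[start : start + k]
            crit = sum(1 for p in critical if match_fn(window[p], motif[p]))
            total = sum(1 for a, b in zip(window, motif) if match_fn(a, b))
            offset = start if strand == "+" else len(seq) - k - start
            candidates.append(
                (-crit, -total, offset, 0 if strand == "+" else 1, strand)
            )
    candidates.sort()
    c = candidates[0]
    return (-c[0], c[4], c[2])
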