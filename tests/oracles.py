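"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (full DP matrices, exhaustive
enumeration) and shares no code with the package's search or scoring paths.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

from dbgalign.extend import OVERSHOOT_SLACK, ScoringScheme
from dbgalign.graph import DeBruijnGraph, canonical, reverse_complement


def nw_full_matrix(a: str, b: str, scheme: ScoringScheme) -> List[List[int]]:
    """Plain-Python global-alignment DP matrix of a (rows) vs b (cols)."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = scheme.gap * i
    for j in range(1, m + 1):
        D[0][j] = scheme.gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            D[i][j] = max(D[i - 1][j - 1] + sub,
                          D[i - 1][j] + scheme.gap,
                          D[i][j - 1] + scheme.gap)
    return D


def nw_prefix_oracle(path_seq: str, s: str, scheme: ScoringScheme) -> Tuple[int, int]:
    """Best score of path_seq vs any prefix of s, and the longest such prefix."""
    D = nw_full_matrix(path_seq, s, scheme)
    last = D[len(path_seq)]
    best = max(last)
    return best, max(j for j, v in enumerate(last) if v == best)


def walk_alignment_score(spelled: str, s: str, scheme: ScoringScheme) -> int:
    """Best global score of s against any prefix of the walk's sequence."""
    D = nw_full_matrix(spelled, s, scheme)
    return max(D[i][len(s)] for i in range(len(spelled) + 1))


def _advance_row(row: List[int], best: int, chars: str, s: str,
                 scheme: ScoringScheme) -> Tuple[List[int], int]:
    """Plain-Python DP row advance, tracking max over rows of row[len(s)]."""
    l = len(s)
    for ch in chars:
        new = [row[0] + scheme.gap]
        for j in range(1, l + 1):
            sub = scheme.match if ch == s[j - 1] else scheme.mismatch
            new.append(max(row[j - 1] + sub, row[j] + scheme.gap,
                           new[j - 1] + scheme.gap))
        row = new
        if row[l] > best:
            best = row[l]
    return row, best


def exhaustive_best_extension(
    graph: DeBruijnGraph,
    v: int,
    s: str,
    scheme: ScoringScheme,
    initial_tail: str = "",
    overshoot_slack: int = OVERSHOOT_SLACK,
    mm=None,
    history: Sequence[int] = (),
    max_walks: int = 50_000,
) -> Optional[int]:
    """Optimal extension score by exhaustive walk enumeration (DFS).

    Enumerates every walk from ``v`` whose committed spelled length stays
    below ``len(s) + overshoot_slack`` (the same finite walk space the
    search explores) and scores each complete-read alignment by a
    plain-Python DP.  Returns None when the instance exceeds ``max_walks``
    walks (caller should skip it).
    """
    if not s:
        return 0
    limit = len(s) + overshoot_slack
    k = graph.k
    l = len(s)
    row0 = [scheme.gap * j for j in range(l + 1)]
    row, best = _advance_row(row0, row0[l], initial_tail[:limit], s, scheme)
    stack = [((v,), row, len(initial_tail[:limit]))]
    walks = 0
    while stack:
        chain, row, consumed, = stack.pop()
        walks += 1
        if walks > max_walks:
            return None
        if consumed >= limit:
            continue
        for head in graph.successors(chain[-1]):
            if mm is not None and not mm.is_transition_valid(
                    tuple(history) + chain, head):
                continue
            chars = graph.oriented_sequence(head)[k - 1:][: limit - consumed]
            new_row, best = _advance_row(row, best, chars, s, scheme)
            stack.append((chain + (head,), new_row, consumed + len(chars)))
    return best


def kmer_graph_oracle(reference: Sequence[str] | str, k: int) -> Tuple[Set[str], Set[Tuple[str, str]]]:
    """Uncompacted canonical k-mer graph: node set and oriented-kmer arcs."""
    if isinstance(reference, str):
        reference = [reference]
    kmers: Set[str] = set()
    for seq in reference:
        for i in range(len(seq) - k + 1):
            kmers.add(canonical(seq[i:i + k]))
    arcs: Set[Tuple[str, str]] = set()
    for km in kmers:
        for okm in (km, reverse_complement(km)):
            for b in "ACGT":
                nxt = okm[1:] + b
                if canonical(nxt) in kmers:
                    arcs.add((okm, nxt))
    return kmers, arcs


def all_maximal_exact_matches(read: str, graph: DeBruijnGraph,
                              min_len: int) -> Set[Tuple[int, int, int, int]]:
    """Quadratic enumeration of maximal read/unitig matches (both strands).

    Returns tuples (read_start, signed_node, offset, length).
    """
    out: Set[Tuple[int, int, int, int]] = set()
    for nid in graph.nodes:
        for signed in (nid, -nid):
            seq = graph.oriented_sequence(signed)
            for i in range(len(read)):
                for j in range(len(seq)):
                    if read[i] != seq[j]:
                        continue
                    if i > 0 and j > 0 and read[i - 1] == seq[j - 1]:
                        continue  # not left-maximal
                    ln = 0
                    while i + ln < len(read) and j + ln < len(seq) \
                            and read[i + ln] == seq[j + ln]:
                        ln += 1
                    if ln >= min_len:
                        out.add((i, signed, j, ln))
    return out
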