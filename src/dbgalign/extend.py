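"""Greedy branch-and-bound seed extension through the graph.

Given a seed ending in node ``v`` and the unaligned remainder ``s`` of the
read, the search explores walks starting at ``v``, maintaining for each
partial walk the full Needleman-Wunsch DP row of its spelled sequence
against ``s``.  Walks are expanded best-first (highest prefix-alignment
score first); a walk is discarded when an admissible upper bound on the
score of any of its extensions cannot beat the best complete alignment
found so far, which preserves optimality while sharply reducing the number
of states visited.  The bound for a partial walk ``w`` is

    max_n  f(w, s[1:n]) + m * (l - n)

i.e. the best prefix alignment score plus a perfect-match score for the
unconsumed read suffix — no extension of ``w`` can do better.

Scoring is classic Needleman-Wunsch with linear gaps (defaults +1 match,
-1 mismatch, -3 gap).  Optionally a trained higher-order Markov model
vetoes extensions whose (state, head) transition does not occur in the
underlying genome.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .graph import DeBruijnGraph, KmerIndex, reverse_complement
from .seeding import find_mems, find_seeds

# chars of path overshoot beyond the read length that the search will spell;
# alignments needing more than this many net insertions are never competitive
# under the default gap penalty
OVERSHOOT_SLACK = 16


@dataclass(frozen=True)
class ScoringScheme:
    """Needleman-Wunsch similarity scores (linear gap model)."""

    match: int = 1
    mismatch: int = -1
    gap: int = -3

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= self.match or self.gap >= 0:
            raise ValueError("require match > 0, mismatch < match, gap < 0")


@dataclass
class AlignmentResult:
    """Outcome of aligning one read to the graph."""

    chain: Tuple[int, ...]
    score: int
    corrected_sequence: str
    aligned: bool
    identity: float
    visited: int = 0
    budget_exhausted: bool = False


@dataclass
class ExtendResult:
    chain: Tuple[int, ...]
    score: int
    path_len: int  # spelled chars (beyond the seed) covered by the best alignment
    visited: int
    budget_exhausted: bool = False


def upper_bound(current_score: int, n: int, l: int, m: int) -> int:
    """Score bound for extending a partial alignment consuming ``n`` of ``l``
    read bases: the current score plus a perfect match on the rest."""
    return current_score + m * (l - n)


def _row_update(row: np.ndarray, path_char: str, s_codes: np.ndarray,
                scheme: ScoringScheme) -> np.ndarray:
    """One DP row step: consume one path character against the whole read."""
    g = scheme.gap
    sub = np.where(s_codes == ord(path_char), scheme.match, scheme.mismatch)
    base = np.empty_like(row)
    base[0] = row[0] + g
    base[1:] = np.maximum(row[1:] + g, row[:-1] + sub)
    # horizontal gap chain via prefix-max of base[j] - g*j
    idx = np.arange(len(row), dtype=row.dtype)
    return np.maximum.accumulate(base - g * idx) + g * idx


def nw_prefix_score(path_seq: str, s: str,
                    scheme: ScoringScheme = ScoringScheme()) -> Tuple[int, int]:
    """Best global alignment score of ``path_seq`` against any prefix of ``s``.

    Returns ``(best_score, prefix_end)`` where ``prefix_end`` is the longest
    read prefix length attaining the maximum.
    """
    l = len(s)
    s_codes = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int64)
    row = scheme.gap * np.arange(l + 1, dtype=np.int64)
    for ch in path_seq:
        row = _row_update(row, ch, s_codes, scheme)
    best = int(row.max())
    prefix_end = int(np.flatnonzero(row == best)[-1])
    return best, prefix_end


def nw_score(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Global Needleman-Wunsch similarity of two full sequences."""
    l = len(b)
    s_codes = np.frombuffer(b.encode(), dtype=np.uint8).astype(np.int64)
    row = scheme.gap * np.arange(l + 1, dtype=np.int64)
    for ch in a:
        row = _row_update(row, ch, s_codes, scheme)
    return int(row[l])


class _State:
    """A partial walk with the DP row of its spelled sequence vs the read."""

    __slots__ = ("chain", "row", "consumed", "score", "prefix_end", "bound",
                 "best_full", "best_path_len", "extendable")

    def __init__(self, chain, row, consumed, score, prefix_end, bound,
                 best_full, best_path_len, extendable):
        self.chain = chain
        self.row = row
        self.consumed = consumed
        self.score = score
        self.prefix_end = prefix_end
        self.bound = bound
        self.best_full = best_full
        self.best_path_len = best_path_len
        self.extendable = extendable

    def sort_key(self):
        # best-first: highest prefix score, then longest consumed prefix,
        # then lexicographically smallest chain (determinism)
        return (-self.score, -self.prefix_end, self.chain)


def _make_state(chain, row, consumed, appended, s_codes, scheme, l, max_consume,
                best_full, best_path_len):
    """Advance ``row`` over ``appended`` path characters, tracking the best
    complete alignment (full read consumed) seen along the way."""
    extendable = True
    if consumed + len(appended) > max_consume:
        appended = appended[: max_consume - consumed]
        extendable = False
    for ch in appended:
        row = _row_update(row, ch, s_codes, scheme)
        consumed += 1
        full = int(row[l])
        if full > best_full:
            best_full, best_path_len = full, consumed
    best = int(row.max())
    prefix_end = int(np.flatnonzero(row == best)[-1])
    m = scheme.match
    bound = int((row + m * (l - np.arange(l + 1))).max())
    return _State(chain, row, consumed, best, prefix_end, bound,
                  best_full, best_path_len, extendable)


def branch_and_bound_extend(
    graph: DeBruijnGraph,
    v: int,
    s: str,
    scheme: ScoringScheme = ScoringScheme(),
    mm=None,
    history: Sequence[int] = (),
    initial_tail: str = "",
    use_bound: bool = True,
    budget: Optional[int] = None,
    overshoot_slack: int = OVERSHOOT_SLACK,
) -> ExtendResult:
    """Find the walk from ``v`` whose spelled sequence best matches ``s``.

    ``initial_tail`` is the part of ``v``'s oriented sequence that lies past
    the seed and therefore belongs to every walk's spelled sequence.
    ``history`` lists the signed nodes preceding ``v`` in the overall chain
    (used only for Markov-model context).  With ``use_bound`` disabled the
    same walk space is searched exhaustively; the result is identical, only
    the number of visited states grows.  ``budget`` caps popped states; when
    exhausted the best walk found so far is returned and flagged.
    """
    if not s:
        return ExtendResult((v,), 0, 0, 0)
    l = len(s)
    k = graph.k
    s_codes = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int64)
    max_consume = l + overshoot_slack
    hist = tuple(history)

    row0 = scheme.gap * np.arange(l + 1, dtype=np.int64)
    # the empty walk prefix is a legal complete alignment (read overhangs a
    # dead end): all of s deleted
    root = _make_state((v,), row0, 0, initial_tail, s_codes, scheme, l,
                       max_consume, int(row0[l]), 0)

    best_full = root.best_full
    best_chain = root.chain
    best_path_len = root.best_path_len
    visited = 0
    budget_exhausted = False

    counter = 0
    pq = [(root.sort_key(), counter, root)]
    while pq:
        _, _, state = heapq.heappop(pq)
        if use_bound and state.bound <= best_full:
            continue
        if budget is not None and visited >= budget:
            budget_exhausted = True
            break
        visited += 1
        if not state.extendable:
            continue
        last = state.chain[-1]
        for head in graph.successors(last):
            if mm is not None and not mm.is_transition_valid(hist + state.chain, head):
                continue
            appended = graph.oriented_sequence(head)[k - 1:]
            child = _make_state(state.chain + (head,), state.row, state.consumed,
                                appended, s_codes, scheme, l, max_consume,
                                best_full, best_path_len)
            if child.best_full > best_full:
                best_full = child.best_full
                best_chain = child.chain
                best_path_len = child.best_path_len
            if use_bound and child.bound <= best_full:
                continue
            counter += 1
            heapq.heappush(pq, (child.sort_key(), counter, child))

    # trim trailing nodes not reached by the best alignment's path prefix
    best_chain = _trim_chain(graph, best_chain, len(initial_tail), best_path_len)
    return ExtendResult(best_chain, best_full, best_path_len, visited, budget_exhausted)


def _trim_chain(graph: DeBruijnGraph, chain: Tuple[int, ...], tail_len: int,
                path_len: int) -> Tuple[int, ...]:
    """Drop chain nodes wholly beyond the aligned path prefix."""
    consumed = tail_len
    keep = 1
    for node in chain[1:]:
        if consumed >= path_len:
            break
        consumed += len(graph.nodes[abs(node)].sequence) - (graph.k - 1)
        keep += 1
    return chain[:keep]


def _mirror(chain: Sequence[int]) -> Tuple[int, ...]:
    return tuple(-x for x in reversed(chain))


def align_read(
    graph: DeBruijnGraph,
    index: KmerIndex,
    read: str,
    scheme: ScoringScheme = ScoringScheme(),
    mm=None,
    config=None,
) -> AlignmentResult:
    """Seed-and-extend alignment of one read; returns the corrected read.

    Seeds are tried longest-first.  For each seed the read remainder to the
    right of the seed is extended through the graph from the seed's node,
    and the left remainder symmetrically on the reverse complement strand
    (one code path for both directions).  The corrected sequence is the
    spelled walk trimmed to the read's aligned span; its identity to the
    read decides the aligned flag.  Reads without any seed are returned
    unaligned and unchanged.
    """
    from .config import Config

    cfg = config or Config()
    read = read.upper()
    l = len(read)
    k = graph.k
    m = scheme.match

    seeds = find_seeds(read, index, graph)
    if not seeds:
        seeds = find_mems(read, graph, cfg.min_mem_length)
    if not seeds:
        return AlignmentResult((), 0, read, False, 0.0)

    fast = _single_diagonal_result(graph, read, seeds, scheme, cfg)
    if fast is not None:
        return fast

    best: Optional[AlignmentResult] = None
    budget_left = cfg.node_visit_budget
    budget_hit = False
    tried = set()

    for seed in seeds[: cfg.seed_retry_cap]:
        diag = (seed.node, seed.offset - seed.read_start)
        if diag in tried:
            continue  # same placement as an already-extended seed
        tried.add(diag)
        node_seq = graph.oriented_sequence(seed.node)
        seed_seq = node_seq[seed.offset: seed.offset + seed.length]

        s_right = read[seed.read_start + seed.length:]
        right = branch_and_bound_extend(
            graph, seed.node, s_right, scheme, mm=mm,
            initial_tail=node_seq[seed.offset + seed.length:],
            use_bound=cfg.use_bound, budget=budget_left,
        )
        budget_left = max(0, budget_left - right.visited)
        budget_hit = budget_hit or right.budget_exhausted

        s_left = reverse_complement(read[: seed.read_start])
        left = branch_and_bound_extend(
            graph, -seed.node, s_left, scheme, mm=mm,
            history=_mirror(right.chain[1:]) if len(right.chain) > 1 else (),
            initial_tail=reverse_complement(node_seq[: seed.offset]),
            use_bound=cfg.use_bound, budget=budget_left,
        )
        budget_left = max(0, budget_left - left.visited)
        budget_hit = budget_hit or left.budget_exhausted

        if mm is not None and len(left.chain) > 1 and len(right.chain) > 1:
            # the first right extension ran without the left flank's context;
            # redo it so the model sees the full walk history across the seed
            right = branch_and_bound_extend(
                graph, seed.node, s_right, scheme, mm=mm,
                history=_mirror(left.chain)[:-1],
                initial_tail=node_seq[seed.offset + seed.length:],
                use_bound=cfg.use_bound, budget=budget_left,
            )
            budget_left = max(0, budget_left - right.visited)
            budget_hit = budget_hit or right.budget_exhausted

        chain = _mirror(left.chain)[:-1] + right.chain
        left_spelled = graph.spell_path(left.chain)
        left_off = len(node_seq) - seed.offset
        left_part = reverse_complement(left_spelled[left_off: left_off + left.path_len])
        right_spelled = graph.spell_path(right.chain)
        right_start = seed.offset + seed.length
        right_part = right_spelled[right_start: right_start + right.path_len]
        corrected = left_part + seed_seq + right_part

        score = nw_score(corrected, read, scheme)
        matches = _match_count(corrected, read)
        identity = matches / l if l else 0.0
        cand = AlignmentResult(chain, score, corrected, identity >= cfg.min_identity,
                               identity, right.visited + left.visited, budget_hit)
        if best is None or cand.score > best.score:
            best = cand
        if best.score >= m * l or budget_left == 0:
            break

    if not best.aligned:
        best = AlignmentResult(best.chain, best.score, read, False,
                               best.identity, best.visited, best.budget_exhausted)
    return best


def _single_diagonal_result(graph, read, seeds, scheme, cfg) -> Optional[AlignmentResult]:
    """Fast path: every seed places the read at one diagonal of one unitig.

    Then the alignment stays within that node, the corrected sequence is the
    node substring on that diagonal, and the score is the ungapped
    comparison (no other graph path shares a single anchor with the read,
    and scattered substitutions never favor a gapped alignment under the
    default gap penalty).  Reads that overhang the node or imply too many
    mismatches fall back to the full search.
    """
    first = seeds[0]
    diag = first.offset - first.read_start
    if any(s.node != first.node or s.offset - s.read_start != diag for s in seeds):
        return None
    if diag < 0:
        return None
    node_seq = graph.oriented_sequence(first.node)
    l = len(read)
    if diag + l > len(node_seq):
        return None
    corrected = node_seq[diag: diag + l]
    matches = sum(a == b for a, b in zip(corrected, read)) if corrected != read else l
    mismatches = l - matches
    if mismatches > 8:
        return None  # unusual error load: let the full DP search decide
    score = scheme.match * matches + scheme.mismatch * mismatches
    if mismatches > 2:
        # with >2 mismatches a gapped alignment could in principle score
        # higher; verify, and defer to the full search if gaps help
        if nw_score(corrected, read, scheme) != score:
            return None
    identity = matches / l if l else 0.0
    if identity < cfg.min_identity:
        return None
    return AlignmentResult((first.node,), score, corrected, True, identity, 0)


def _match_count(a: str, b: str) -> int:
    """Number of identical aligned bases in a minimum-edit-distance alignment."""
    if a == b:
        return len(a)
    try:
        import edlib
    except ImportError:
        return _match_count_dp(a, b)
    cigar = edlib.align(a, b, task="path")["cigar"] or ""
    if "=" not in cigar and "X" not in cigar:
        return _match_count_dp(a, b)
    matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                matches += int(num)
            num = ""
    return matches


def _match_count_dp(a: str, b: str) -> int:
    """Matches in an optimal unit-cost alignment, by full DP (small inputs)."""
    n, m_ = len(a), len(b)
    prev = list(range(m_ + 1))
    prev_match = [0] * (m_ + 1)
    for i in range(1, n + 1):
        cur = [i] + [0] * m_
        cur_match = [0] * (m_ + 1)
        for j in range(1, m_ + 1):
            eq = a[i - 1] == b[j - 1]
            best = prev[j - 1] + (0 if eq else 1)
            bm = prev_match[j - 1] + (1 if eq else 0)
            if prev[j] + 1 < best or (prev[j] + 1 == best and prev_match[j] > bm):
                best, bm = prev[j] + 1, prev_match[j]
            if cur[j - 1] + 1 < best or (cur[j - 1] + 1 == best and cur_match[j - 1] > bm):
                best, bm = cur[j - 1] + 1, cur_match[j - 1]
            cur[j], cur_match[j] = best, bm
        prev, prev_match = cur, cur_match
    return prev_match[m_]
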