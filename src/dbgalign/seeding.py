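"""Seed finding: exact k-mer anchors with a sub-k MEM fallback.

The primary pathway looks up every k-mer of the read in the graph's k-mer
index and merges runs of hits that are contiguous in both the read and a
single unitig.  Reads whose errors are spaced more tightly than k share no
k-mer with the graph; for those, maximal exact matches (MEMs) shorter than
k between the read and the unitigs serve as fallback anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from .graph import DeBruijnGraph, KmerIndex


@dataclass(frozen=True)
class Seed:
    """An exact match anchoring a read substring to one graph location.

    ``node`` is a signed unitig id; ``offset`` is the match start within
    that signed node's oriented sequence.  ``exact`` distinguishes merged
    k-mer-chain seeds from MEM fallback seeds.
    """

    read_start: int
    node: int
    offset: int
    length: int
    exact: bool = True


def _sort_seeds(seeds: List[Seed]) -> List[Seed]:
    # longest first; ties by read position then node id for determinism
    return sorted(seeds, key=lambda s: (-s.length, s.read_start, abs(s.node), s.node < 0))


def find_seeds(read: str, index: KmerIndex, graph: DeBruijnGraph) -> List[Seed]:
    """Exact k-mer seeds of a read, merged into maximal within-unitig runs.

    Consecutive read k-mers hitting consecutive offsets of the same signed
    node merge into a single seed; a run crossing a unitig boundary is split
    there (extension across arcs is the extension phase's job).  Returns
    seeds sorted by decreasing length; empty list when no read k-mer is
    present in the graph.
    """
    k = graph.k
    if len(read) < k:
        return []
    seeds: List[Seed] = []
    run_start = None  # (read_start, node, offset)
    prev = None  # (i, node, offset)
    for i in range(len(read) - k + 1):
        hit = index.lookup(read[i:i + k])
        if hit is not None:
            node, offset = hit
            if (
                prev is not None
                and prev[0] == i - 1
                and prev[1] == node
                and prev[2] == offset - 1
            ):
                prev = (i, node, offset)
                continue
            if run_start is not None:
                seeds.append(_close_run(run_start, prev, k))
            run_start = (i, node, offset)
            prev = (i, node, offset)
        else:
            if run_start is not None:
                seeds.append(_close_run(run_start, prev, k))
                run_start = prev = None
    if run_start is not None:
        seeds.append(_close_run(run_start, prev, k))
    return _sort_seeds(seeds)


def _close_run(run_start, last, k: int) -> Seed:
    read_start, node, offset = run_start
    length = (last[0] - read_start) + k
    return Seed(read_start, node, offset, length, exact=True)


def find_mems(read: str, graph: DeBruijnGraph, min_mem_length: int = 15) -> List[Seed]:
    """Maximal exact matches between the read and any oriented unitig.

    A MEM is an exact read/unitig match extensible on neither side.  Only
    matches of at least ``min_mem_length`` bases are reported, sorted by
    decreasing length.  Intended as a fallback when :func:`find_seeds`
    returns nothing, in which case every MEM is necessarily shorter than k.

    Anchoring uses a hash of all ``min_mem_length``-mers of the unitigs with
    bidirectional extension; on the genome sizes this package targets that
    is equivalent to (and simpler than) a suffix-array scan.
    """
    w = min_mem_length
    if w < 1 or len(read) < w:
        return []
    anchors: Dict[str, List[tuple]] = {}
    for nid in graph.nodes:
        for signed in (nid, -nid):
            seq = graph.oriented_sequence(signed)
            for j in range(len(seq) - w + 1):
                anchors.setdefault(seq[j:j + w], []).append((signed, j))

    found = set()
    for i in range(len(read) - w + 1):
        for signed, j in anchors.get(read[i:i + w], ()):
            seq = graph.oriented_sequence(signed)
            a, b = i, j
            while a > 0 and b > 0 and read[a - 1] == seq[b - 1]:
                a -= 1
                b -= 1
            e_r, e_u = i + w, j + w
            while e_r < len(read) and e_u < len(seq) and read[e_r] == seq[e_u]:
                e_r += 1
                e_u += 1
            found.add((a, signed, b, e_r - a))
    seeds = [Seed(rs, node, off, ln, exact=False) for rs, node, off, ln in found]
    return _sort_seeds(seeds)
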