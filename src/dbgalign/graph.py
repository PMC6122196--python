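"""Bidirected, unitig-compacted de Bruijn graph built from a reference.

Nodes are unitigs: maximal non-branching chains of k-mers contracted into a
single sequence of length >= k.  Each unitig is stored once in an arbitrary
"forward" orientation; a *signed* node identifier (+id / -id) selects the
forward or reverse-complement orientation.  Arcs connect signed nodes and
always represent an exact overlap of k-1 bases between the oriented
sequences, so every walk through the graph spells a DNA sequence
unambiguously.  Because the graph is built from a known reference it is
complete and error-free: every reference substring of length >= k spells a
walk in the graph.

k must be odd so that no k-mer equals its own reverse complement, which lets
every k-mer be identified with a single canonical (lexicographically minimal)
form stored exactly once.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_SPLIT_NON_ACGT = re.compile(r"[^ACGT]+")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class Unitig:
    """A maximal non-branching chain of k-mers, stored in forward orientation."""

    id: int
    sequence: str
    multiplicity: Optional[int] = None

    def __len__(self) -> int:
        return len(self.sequence)


class DeBruijnGraph:
    """Unitig graph with signed (strand-aware) node identifiers.

    ``nodes`` maps positive integer ids to :class:`Unitig`.  Arcs are stored
    as successor lists on signed ids; an arc ``(u, v)`` always has the
    mirrored arc ``(-v, -u)``, so traversal code never needs to special-case
    strand.
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self.nodes: Dict[int, Unitig] = {}
        self._succ: Dict[int, List[int]] = {}

    # -- topology ----------------------------------------------------------

    def add_node(self, unitig: Unitig) -> None:
        if unitig.id <= 0:
            raise ValueError("node ids must be positive")
        self.nodes[unitig.id] = unitig

    def add_arc(self, u: int, v: int) -> None:
        """Add arc u->v and its reverse-complement mirror -v->-u."""
        for a, b in ((u, v), (-v, -u)):
            succ = self._succ.setdefault(a, [])
            if b not in succ:
                succ.append(b)
                succ.sort()

    def successors(self, signed_id: int) -> Tuple[int, ...]:
        return tuple(self._succ.get(signed_id, ()))

    def predecessors(self, signed_id: int) -> Tuple[int, ...]:
        return tuple(-u for u in self._succ.get(-signed_id, ()))

    def has_arc(self, u: int, v: int) -> bool:
        return v in self._succ.get(u, ())

    def num_arcs(self) -> int:
        # mirrored arcs counted once
        seen = set()
        for u, vs in self._succ.items():
            for v in vs:
                if (-v, -u) not in seen:
                    seen.add((u, v))
        return len(seen)

    # -- sequence ----------------------------------------------------------

    def oriented_sequence(self, signed_id: int) -> str:
        seq = self.nodes[abs(signed_id)].sequence
        return seq if signed_id > 0 else reverse_complement(seq)

    def spell_path(self, chain: Sequence[int]) -> str:
        """Spell the DNA sequence of a walk, collapsing k-1 overlaps.

        Raises ``ValueError`` if consecutive chain elements are not joined
        by an arc (the node list would not describe a walk).
        """
        if not chain:
            return ""
        parts = [self.oriented_sequence(chain[0])]
        for prev, cur in zip(chain, chain[1:]):
            if not self.has_arc(prev, cur):
                raise ValueError(f"no arc between signed nodes {prev} and {cur}")
            parts.append(self.oriented_sequence(cur)[self.k - 1:])
        return "".join(parts)

    def total_sequence_length(self) -> int:
        """Summed unitig length over one strand."""
        return sum(len(u.sequence) for u in self.nodes.values())

    # -- GFA1 serialization -------------------------------------------------

    def to_gfa(self, path: str) -> None:
        """Write the graph as GFA1 (S-lines, L-lines with (k-1)M overlap)."""
        with open(path, "w") as fh:
            fh.write(f"H\tVN:Z:1.0\tKM:i:{self.k}\n")
            for nid in sorted(self.nodes):
                u = self.nodes[nid]
                mult = f"\tRC:i:{u.multiplicity}" if u.multiplicity is not None else ""
                fh.write(f"S\t{nid}\t{u.sequence}{mult}\n")
            written = set()
            for u in sorted(self._succ):
                for v in self._succ[u]:
                    if (-v, -u) in written:
                        continue
                    written.add((u, v))
                    fh.write(
                        "L\t{}\t{}\t{}\t{}\t{}M\n".format(
                            abs(u), "+" if u > 0 else "-",
                            abs(v), "+" if v > 0 else "-",
                            self.k - 1,
                        )
                    )

    @classmethod
    def from_gfa(cls, path: str) -> "DeBruijnGraph":
        k = None
        nodes = []
        links = []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "H":
                    for tag in fields[1:]:
                        if tag.startswith("KM:i:"):
                            k = int(tag[5:])
                elif fields[0] == "S":
                    mult = None
                    for tag in fields[3:]:
                        if tag.startswith("RC:i:"):
                            mult = int(tag[5:])
                    nodes.append(Unitig(int(fields[1]), fields[2], mult))
                elif fields[0] == "L":
                    u = int(fields[1]) * (1 if fields[2] == "+" else -1)
                    v = int(fields[3]) * (1 if fields[4] == "+" else -1)
                    links.append((u, v))
        if k is None:
            raise ValueError("GFA header lacks KM:i tag with the k-mer size")
        g = cls(k)
        for u in nodes:
            g.add_node(u)
        for a, b in links:
            g.add_arc(a, b)
        return g


class KmerIndex:
    """Hash index from canonical k-mer to its unique graph location.

    ``lookup`` resolves any k-mer (either strand) to ``(signed node id,
    offset)`` such that the oriented sequence of that signed node contains
    the query k-mer verbatim at the given offset.
    """

    def __init__(self, k: int) -> None:
        self.k = k
        self._table: Dict[str, Tuple[int, int, bool]] = {}
        self._len: Dict[int, int] = {}

    def __len__(self) -> int:
        return len(self._table)

    def add(self, kmer: str, node_id: int, offset: int) -> None:
        canon = canonical(kmer)
        self._table[canon] = (node_id, offset, canon == kmer)

    def lookup(self, kmer: str) -> Optional[Tuple[int, int]]:
        canon = canonical(kmer)
        entry = self._table.get(canon)
        if entry is None:
            return None
        node_id, offset, canon_is_fwd = entry
        query_is_fwd = (kmer == canon) == canon_is_fwd
        if query_is_fwd:
            return node_id, offset
        # query matches the reverse-oriented unitig
        return -node_id, self._len[node_id] - self.k - offset

    # node lengths are registered so reverse-strand offsets can be computed
    # without holding a graph reference
    def register_node_length(self, node_id: int, length: int) -> None:
        self._len[node_id] = length

    def to_json(self, path: str) -> None:
        payload = {
            "k": self.k,
            "lengths": self._len,
            "table": {km: [n, off, fwd] for km, (n, off, fwd) in self._table.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "KmerIndex":
        with open(path) as fh:
            payload = json.load(fh)
        idx = cls(payload["k"])
        idx._len = {int(n): l for n, l in payload["lengths"].items()}
        idx._table = {km: (n, off, fwd) for km, (n, off, fwd) in payload["table"].items()}
        return idx


def _reference_fragments(reference: Iterable[str] | str) -> List[str]:
    if isinstance(reference, str):
        reference = [reference]
    frags: List[str] = []
    for seq in reference:
        for frag in _SPLIT_NON_ACGT.split(seq.upper()):
            if frag:
                frags.append(frag)
    return frags


def build_graph(reference: Iterable[str] | str, k: int = 31,
                annotate_multiplicity: bool = False) -> DeBruijnGraph:
    """Build the unitig-compacted de Bruijn graph of a reference.

    Parameters
    ----------
    reference:
        One DNA string or an iterable of DNA strings.  Characters outside
        ACGT split a sequence into independently processed fragments.
    k:
        Odd word length >= 3.
    annotate_multiplicity:
        When true, each unitig records how often its sequence (either strand)
        occurs in the reference; purely diagnostic.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 3")
    frags = _reference_fragments(reference)
    if not frags:
        raise ValueError("empty reference")
    if all(len(f) < k for f in frags):
        raise ValueError(f"no reference fragment reaches the k-mer size {k}")

    kmers = set()
    for frag in frags:
        for i in range(len(frag) - k + 1):
            kmers.add(canonical(frag[i:i + k]))

    def fw_neighbors(okmer: str) -> List[str]:
        out = []
        suffix = okmer[1:]
        for b in "ACGT":
            nxt = suffix + b
            if canonical(nxt) in kmers:
                out.append(nxt)
        return out

    def bw_neighbors(okmer: str) -> List[str]:
        out = []
        prefix = okmer[:-1]
        for b in "ACGT":
            prv = b + prefix
            if canonical(prv) in kmers:
                out.append(prv)
        return out

    # walk maximal non-branching chains of oriented k-mers
    assigned = set()
    unitig_seqs: List[str] = []
    for start in sorted(kmers):
        if start in assigned:
            continue
        chain = [start]
        used = {start}
        # extend forward
        cur = start
        while True:
            fw = fw_neighbors(cur)
            if len(fw) != 1:
                break
            nxt = fw[0]
            if len(bw_neighbors(nxt)) != 1:
                break
            cn = canonical(nxt)
            if cn in used or cn in assigned:
                break  # cycle or already consumed
            chain.append(nxt)
            used.add(cn)
            cur = nxt
        # extend backward from the start
        cur = start
        prefix_chain: List[str] = []
        while True:
            bw = bw_neighbors(cur)
            if len(bw) != 1:
                break
            prv = bw[0]
            if len(fw_neighbors(prv)) != 1:
                break
            cn = canonical(prv)
            if cn in used or cn in assigned:
                break
            prefix_chain.append(prv)
            used.add(cn)
            cur = prv
        chain = prefix_chain[::-1] + chain
        seq = chain[0] + "".join(okmer[-1] for okmer in chain[1:])
        assigned.update(canonical(c) for c in chain)
        unitig_seqs.append(min(seq, reverse_complement(seq)))

    graph = DeBruijnGraph(k)
    for nid, seq in enumerate(sorted(unitig_seqs), start=1):
        graph.add_node(Unitig(nid, seq))

    index = index_kmers(graph)
    graph.kmer_index = index  # cached; rebuildable via index_kmers

    # arcs: for each oriented unitig end, probe all four one-base extensions
    for nid, unitig in graph.nodes.items():
        for signed in (nid, -nid):
            oseq = graph.oriented_sequence(signed)
            last = oseq[-k:]
            suffix = last[1:]
            for b in "ACGT":
                probe = suffix + b
                hit = index.lookup(probe)
                if hit is None:
                    continue
                target, offset = hit
                if offset == 0:
                    graph.add_arc(signed, target)

    if annotate_multiplicity:
        text = "$".join(frags)
        for unitig in graph.nodes.values():
            s = unitig.sequence
            rc = reverse_complement(s)
            count = _count_occurrences(text, s)
            if rc != s:
                count += _count_occurrences(text, rc)
            unitig.multiplicity = count
    return graph


def _count_occurrences(text: str, pattern: str) -> int:
    count = start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return count
        count += 1
        start = i + 1  # overlapping occurrences count


def index_kmers(graph: DeBruijnGraph) -> KmerIndex:
    """Index every k-mer of every unitig for O(1) seeding lookups."""
    idx = KmerIndex(graph.k)
    for nid, unitig in graph.nodes.items():
        idx.register_node_length(nid, len(unitig.sequence))
        seq = unitig.sequence
        for off in range(len(seq) - graph.k + 1):
            idx.add(seq[off:off + graph.k], nid, off)
    return idx


def spell_path(graph: DeBruijnGraph, chain: Sequence[int]) -> str:
    """Module-level convenience wrapper for :meth:`DeBruijnGraph.spell_path`."""
    return graph.spell_path(chain)
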