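"""Higher-order Markov model over graph walks for implicit repeat resolution.

Although every arc of the graph joins two consecutive k-mers of the genome,
a walk through three or more nodes need not spell a genomic substring.  The
model records, per order n in [2, maxOrder], which n-node walk states were
observed continuing into which head node during a first, unconstrained
alignment pass.  Transitions are filtered with a Poisson likelihood-ratio
test separating misalignment artifacts (expected frequency ~1) from genuine
genomic paths (expected frequency C_M, the coverage-derived expectation for
a path spelling M bases), and a state is only allowed to veto continuations
when C_M is high enough (>= minChainCov) that a genuine path would almost
surely have been observed.

The actual transition probabilities are incidental: what matters is whether
a transition's probability is zero (path absent from the genome, skipped
during the second, guided alignment pass) or positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .graph import DeBruijnGraph

logger = logging.getLogger(__name__)


@dataclass
class MMParams:
    """Training/query parameters of the Markov model.

    ``max_order`` bounds the state length in nodes; ``min_likelihood_ratio``
    is the pruning threshold of the Poisson test; ``min_chain_cov`` the
    minimum expected path coverage for a state to restrict the search;
    ``read_length`` and ``coverage`` parameterize the coverage model.
    """

    max_order: int = 10
    min_likelihood_ratio: float = 1e5
    min_chain_cov: float = 10.0
    read_length: int = 0
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.max_order < 2:
            raise ValueError("max_order must be >= 2")
        if self.min_likelihood_ratio <= 0 or self.min_chain_cov <= 0:
            raise ValueError("thresholds must be positive")


def expected_coverage(l: int, M: int, c: float) -> float:
    """Expected number of reads fully covering a path spelling M bases.

    C_M = c * (l - M + 1) / l for a path of multiplicity one, with C_1 = c;
    zero when the path is longer than a read.
    """
    if l <= 0:
        raise ValueError("read length must be positive")
    if M < 1 or c < 0:
        raise ValueError("require M >= 1 and c >= 0")
    return max(0.0, c * (l - M + 1) / l)


def likelihood_ratio(freq: int, C_M: float) -> float:
    """Poisson likelihood ratio P(freq | lambda=1) / P(freq | lambda=C_M).

    Large values support the hypothesis that the observed path has
    multiplicity zero in the genome (a misalignment artifact).  Closed
    form: exp(C_M - 1) * C_M**(-freq), evaluated in log space.
    """
    if freq < 1:
        raise ValueError("only observed paths (freq >= 1) are tested")
    if C_M <= 0:
        raise ValueError("C_M must be positive")
    return math.exp((C_M - 1.0) - freq * math.log(C_M))


class MarkovModel:
    """Per-order tables of observed walk states and their continuations."""

    def __init__(self, params: MMParams, graph: Optional[DeBruijnGraph] = None) -> None:
        self.params = params
        self.graph = graph
        # order -> state tuple -> head -> count
        self.tables: Dict[int, Dict[Tuple[int, ...], Dict[int, int]]] = {}
        # filled after pruning: order -> state -> head -> probability
        self.probabilities: Dict[int, Dict[Tuple[int, ...], Dict[int, float]]] = {}
        self._spell_len_cache: Dict[Tuple[int, ...], int] = {}

    # -- observation ------------------------------------------------------

    def observe_chain(self, chain: Sequence[int]) -> None:
        """Count every contiguous (n+1)-node subchain of an alignment walk,
        for each order n, in both the walk's and its mirror orientation."""
        for oriented in (tuple(chain), tuple(-x for x in reversed(chain))):
            w = len(oriented)
            for n in range(2, min(self.params.max_order, w - 1) + 1):
                table = self.tables.setdefault(n, {})
                for i in range(w - n):
                    state = oriented[i:i + n]
                    head = oriented[i + n]
                    heads = table.setdefault(state, {})
                    heads[head] = heads.get(head, 0) + 1

    # -- coverage model ----------------------------------------------------

    def _witness_span(self, path: Tuple[int, ...]) -> int:
        """Read span (bases) needed to witness a walk through ``path``.

        A read's chain contains the path's nodes consecutively as soon as it
        covers one base exclusive to the first node, all middle nodes, and
        one base exclusive to the last node.  That span — not the full
        spelled path, whose terminal unitigs may be far longer than any
        read — is what the coverage expectation C_M must describe for the
        Poisson frequency model to match the counting rule.
        """
        if path not in self._spell_len_cache:
            k = self.graph.k
            middle = path[1:-1]
            span = 2  # one base exclusive to each terminal node
            if middle:
                span += len(self.graph.nodes[abs(middle[0])].sequence)
                for node in middle[1:]:
                    span += len(self.graph.nodes[abs(node)].sequence) - (k - 1)
            self._spell_len_cache[path] = span
        return self._spell_len_cache[path]

    def _expected_path_coverage(self, path: Tuple[int, ...]) -> float:
        M = self._witness_span(path)
        l = self.params.read_length
        if l <= 0:
            return 0.0
        if M > l:
            return 0.0
        return expected_coverage(l, M, self.params.coverage)

    # -- pruning -----------------------------------------------------------

    def prune(self) -> int:
        """Apply the likelihood-ratio test to every observed transition and
        convert surviving counts to probabilities.  Returns the number of
        pruned transitions."""
        pruned = 0
        for n, table in self.tables.items():
            for state in list(table):
                heads = table[state]
                for head in list(heads):
                    C_M = self._expected_path_coverage(state + (head,))
                    if C_M <= 0:
                        continue  # untestable; also unusable at query time
                    lr = likelihood_ratio(heads[head], C_M)
                    if lr >= self.params.min_likelihood_ratio:
                        del heads[head]
                        pruned += 1
                if not heads:
                    del table[state]
        self.probabilities = {
            n: {
                state: {h: c / total for h, c in heads.items()}
                for state, heads in table.items()
                if (total := sum(heads.values()))
            }
            for n, table in self.tables.items()
        }
        return pruned

    # -- query -------------------------------------------------------------

    def is_transition_valid(self, history: Sequence[int], head: int) -> bool:
        """Whether extending the walk ``history`` with ``head`` is allowed.

        Orders are examined from the highest usable one downward: the first
        order whose trailing-state is both present in its table and usable
        (C_M of the state+head path >= minChainCov) decides.  When no order
        decides, the transition is unrestricted (valid).
        """
        hist = tuple(history)
        top = min(self.params.max_order, len(hist))
        for n in range(top, 1, -1):
            table = self.tables.get(n)
            if not table:
                continue
            state = hist[-n:]
            heads = table.get(state)
            if heads is None:
                continue
            if self._expected_path_coverage(state + (head,)) < self.params.min_chain_cov:
                continue
            return head in heads
        return True

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str) -> None:
        """Sidecar format: order, comma-separated state, head, count,
        probability, usable flag (one line per surviving transition)."""
        with open(path, "w") as fh:
            fh.write(f"#read_length={self.params.read_length}\t"
                     f"coverage={self.params.coverage}\t"
                     f"max_order={self.params.max_order}\t"
                     f"min_likelihood_ratio={self.params.min_likelihood_ratio}\t"
                     f"min_chain_cov={self.params.min_chain_cov}\n")
            fh.write("order\tstate\thead\tcount\tprobability\tusable\n")
            for n in sorted(self.tables):
                for state in sorted(self.tables[n]):
                    for head, count in sorted(self.tables[n][state].items()):
                        usable = self._expected_path_coverage(state + (head,)) \
                            >= self.params.min_chain_cov
                        prob = self.probabilities.get(n, {}).get(state, {}).get(head, 0.0)
                        fh.write("{}\t{}\t{}\t{}\t{:.6g}\t{}\n".format(
                            n, ",".join(map(str, state)), head, count, prob, int(usable)))

    @classmethod
    def from_tsv(cls, path: str, graph: DeBruijnGraph) -> "MarkovModel":
        params = MMParams()
        mm = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    kv = dict(item.split("=", 1) for item in line[1:].split("\t"))
                    params = MMParams(
                        max_order=int(kv["max_order"]),
                        min_likelihood_ratio=float(kv["min_likelihood_ratio"]),
                        min_chain_cov=float(kv["min_chain_cov"]),
                        read_length=int(kv["read_length"]),
                        coverage=float(kv["coverage"]),
                    )
                    mm = cls(params, graph)
                    continue
                if line.startswith("order\t") or not line:
                    continue
                n_s, state_s, head_s, count_s, prob_s, _ = line.split("\t")
                n = int(n_s)
                state = tuple(int(x) for x in state_s.split(","))
                mm.tables.setdefault(n, {}).setdefault(state, {})[int(head_s)] = int(count_s)
        if mm is None:
            raise ValueError("model file lacks the parameter header line")
        mm.probabilities = {
            n: {
                state: {h: c / total for h, c in heads.items()}
                for state, heads in table.items()
                if (total := sum(heads.values()))
            }
            for n, table in mm.tables.items()
        }
        return mm

    def num_transitions(self) -> int:
        return sum(len(h) for t in self.tables.values() for h in t.values())


def train(
    graph: DeBruijnGraph,
    reads: Iterable[str],
    scheme=None,
    params: Optional[MMParams] = None,
    index=None,
    config=None,
    chains: Optional[List[Tuple[Tuple[int, ...], int]]] = None,
) -> MarkovModel:
    """Train the model from a first, unconstrained alignment pass.

    Each read is aligned with no Markov restriction; every aligned read's
    best chain contributes one observation per contiguous (n+1)-node
    subchain, in both orientations.  Coverage c is estimated as total
    aligned read bases over total unitig length (one strand), and the read
    length for the coverage model is the modal input read length.  Callers
    that already ran the first pass can supply ``chains`` as a list of
    ``(chain, read_length)`` pairs to avoid re-aligning.
    """
    from .config import Config
    from .extend import ScoringScheme, align_read
    from .graph import index_kmers

    cfg = config or Config()
    scheme = scheme or ScoringScheme(cfg.match, cfg.mismatch, cfg.gap)
    params = params or MMParams(cfg.max_order, cfg.min_likelihood_ratio, cfg.min_chain_cov)

    if chains is None:
        if index is None:
            index = index_kmers(graph)
        chains = []
        for read in reads:
            res = align_read(graph, index, read, scheme, mm=None, config=cfg)
            if res.aligned:
                chains.append((res.chain, len(read)))

    mm = MarkovModel(params, graph)
    if not chains:
        logger.warning("no aligned reads: Markov model is empty and restricts nothing")
        return mm

    lengths: Dict[int, int] = {}
    aligned_bases = 0
    for _, rl in chains:
        lengths[rl] = lengths.get(rl, 0) + 1
        aligned_bases += rl
    params.read_length = max(lengths, key=lambda rl: (lengths[rl], rl))
    params.coverage = aligned_bases / max(1, graph.total_sequence_length())

    for chain, _ in chains:
        if len(chain) >= 3:
            mm.observe_chain(chain)
    mm.prune()
    return mm


def is_transition_valid(mm: MarkovModel, history: Sequence[int], head: int) -> bool:
    """Module-level wrapper for :meth:`MarkovModel.is_transition_valid`."""
    return mm.is_transition_valid(history, head)
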