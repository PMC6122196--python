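"""Shared fixtures: small random instances and the branch-and-rejoin genome."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dbgalign import build_graph, index_kmers
from dbgalign.graph import reverse_complement

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_read(rng: np.random.Generator, read: str, pattern: str) -> str:
    """Apply one of four error patterns: none / sub / ins / del."""
    if pattern == "none" or not read:
        return read
    pos = int(rng.integers(0, len(read)))
    if pattern == "sub":
        alt = BASES.replace(read[pos], "")
        return read[:pos] + alt[int(rng.integers(3))] + read[pos + 1:]
    if pattern == "ins":
        return read[:pos] + BASES[int(rng.integers(4))] + read[pos:]
    if pattern == "del":
        return read[:pos] + read[pos + 1:]
    raise ValueError(pattern)


def repetitive_reference(rng: np.random.Generator, length: int, k: int) -> str:
    """A short reference with an internal repeat so the graph branches."""
    core = random_dna(rng, max(k + 2, length // 5))
    a, b, c = (random_dna(rng, max(k, length // 4)) for _ in range(3))
    return a + core + b + core + c


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def branchy_instance(rng):
    """Small branchy graph plus its generating reference (k=7)."""
    ref = repetitive_reference(rng, 120, 7)
    graph = build_graph(ref, 7)
    return ref, graph, index_kmers(graph)


def fig1_genome(rng: np.random.Generator, core_len: int = 45, b_len: int = 40,
                flank_len: int = 300):
    """Genome realizing the classic branch-and-rejoin repeat topology.

    Three genomic paths share a repeated core A: F-B-A-D, G-B-A-E and
    C-A-E.  Order-2 context at A distinguishes C (which always continues
    to E) but not B (which continues to D or E depending on whether the
    walk came through F or G); order-3 context resolves that too.  The
    core and B sizes keep the corresponding witness spans under the
    coverage-gate bound for 150 bp reads at 25x, so every table order the
    topology needs is actually usable.

    Returns (genome_sequences, labels) with labels mapping region names to
    their sequences.
    """
    core = random_dna(rng, core_len)    # A: shared core, repeated 4x
    ctx_b = random_dna(rng, b_len)      # B: shared mid context (via F or G)
    ctx_c = random_dna(rng, b_len)      # C: shared mid context (via H1 or H2)
    f, g, d, e, h1, h2 = (random_dna(rng, flank_len) for _ in range(6))
    seq1 = f + ctx_b + core + d
    seq2 = g + ctx_b + core + e
    seq3 = h1 + ctx_c + core + e
    seq4 = h2 + ctx_c + core + e
    # every walk through C continues to E, so the order-3 rows (H*,C,A) are
    # redundant with the order-2 row (C,A) — the figure's redundancy remark
    return [seq1, seq2, seq3, seq4], {
        "A": core, "B": ctx_b, "C": ctx_c, "D": d, "E": e, "F": f, "G": g,
        "H1": h1, "H2": h2,
    }
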