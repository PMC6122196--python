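"""Synthetic genomes, Illumina-like read simulation, and accuracy scoring.

The genome generator plants exact or slightly diverged repeat copies in an
i.i.d.-uniform background so that graph construction produces the classic
branch-and-rejoin repeat topology whose resolution the Markov model is for.
The read simulator emulates an ART-style Illumina model at the level the
aligner cares about: fixed-length reads drawn uniformly from both strands,
uniform per-base substitution errors (typically 1-2%), optional uniform
indels, and an error-free twin recorded for every read as evaluation ground
truth.  Position-dependent error profiles and quality-model realism are
deliberately not emulated; qualities are written as constant Q40.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .graph import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatSpec:
    """Recipe for a background genome with planted repeats."""

    genome_length: int
    repeat_length: int = 0
    repeat_copies: int = 0
    divergence: float = 0.0  # per-base substitution rate between repeat copies
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeat_copies and self.repeat_length * self.repeat_copies >= self.genome_length:
            raise ValueError("repeats would exceed the genome length")
        if not 0.0 <= self.divergence <= 0.05:
            raise ValueError("divergence must lie in [0, 0.05]")


@dataclass
class SimulatedRead:
    """An erroneous read paired with its error-free twin and origin."""

    read: str
    qualities: str
    error_free: str
    sequence_id: str
    start: int
    strand: str  # '+' or '-'


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def generate_genome(spec: RepeatSpec) -> str:
    """Deterministic synthetic genome with non-overlapping planted repeats.

    Repeat copies are placed with a guard gap between them so every copy has
    distinct flanking context (the graph then shows one high-multiplicity
    unitig with branching at both ends).  Raises when the requested copies
    cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genome = bytearray(_random_dna(rng, spec.genome_length).encode())
    if spec.repeat_copies:
        repeat = _random_dna(rng, spec.repeat_length)
        gap = 64  # distinct flanks around each copy
        positions: List[int] = []
        for _ in range(10000):
            if len(positions) == spec.repeat_copies:
                break
            p = int(rng.integers(0, spec.genome_length - spec.repeat_length + 1))
            if all(abs(p - q) >= spec.repeat_length + gap for q in positions):
                positions.append(p)
        else:
            raise ValueError("could not place repeat copies without overlap")
        for p in sorted(positions):
            copy = repeat
            if spec.divergence > 0:
                copy = _mutate(rng, repeat, spec.divergence)
            genome[p:p + spec.repeat_length] = copy.encode()
    return genome.decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    genome: str,
    read_length: int,
    coverage: float,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    rng_seed: int = 0,
    sequence_id: str = "genome",
) -> List[SimulatedRead]:
    """Uniform shotgun sampling with per-base substitution/indel errors.

    The read count is round(coverage * genome_length / read_length); starts
    are uniform over valid positions and strands are uniform.  Substitutions
    replace a base with one of the three alternatives uniformly; insertions
    add a uniform base, deletions drop one (so with indels the read length
    may differ from the twin's).  The error-free twin is the genome
    substring at the origin, in read orientation.
    """
    if read_length > len(genome):
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(rng_seed)
    n_reads = int(round(coverage * len(genome) / read_length))
    reads: List[SimulatedRead] = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(genome) - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        twin = genome[start:start + read_length]
        if strand == "-":
            twin = reverse_complement(twin)
        read = _apply_errors(rng, twin, sub_rate, indel_rate)
        reads.append(SimulatedRead(read, "I" * len(read), twin, sequence_id, start, strand))
    return reads


def _apply_errors(rng: np.random.Generator, seq: str, sub_rate: float,
                  indel_rate: float) -> str:
    if sub_rate <= 0 and indel_rate <= 0:
        return seq
    out: List[str] = []
    for ch in seq:
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                out.append(chr(_BASES[rng.integers(4)]))  # insertion before ch
                out.append(ch)
            # else deletion: drop ch
            continue
        if sub_rate > 0 and rng.random() < sub_rate:
            alt = [b for b in "ACGT" if b != ch]
            out.append(alt[int(rng.integers(3))])
        else:
            out.append(ch)
    return "".join(out)


def evaluate(
    corrected: Sequence[str],
    error_free: Sequence[str],
    raw_reads: Optional[Sequence[str]] = None,
    multi_node: Optional[Sequence[bool]] = None,
    aligned: Optional[Sequence[bool]] = None,
) -> Dict[str, float]:
    """Fraction of correctly aligned reads.

    A read is correct iff its corrected sequence equals the error-free twin.
    Unaligned reads (flag given) count as correct only when the raw read
    already equals the twin.  When per-read multi-node flags are supplied,
    the report also restricts to reads whose alignment walk spans at least
    two nodes — the stratum where path choice actually matters.
    """
    if len(corrected) != len(error_free):
        raise ValueError("corrected and error-free inputs differ in cardinality")
    n = len(corrected)
    correct_flags = []
    for i in range(n):
        if aligned is not None and not aligned[i]:
            raw = raw_reads[i] if raw_reads is not None else corrected[i]
            correct_flags.append(raw == error_free[i])
        else:
            correct_flags.append(corrected[i] == error_free[i])
    report: Dict[str, float] = {
        "n_reads": n,
        "n_correct": int(sum(correct_flags)),
        "pct_correct": 100.0 * sum(correct_flags) / n if n else 0.0,
    }
    if multi_node is not None:
        idx = [i for i in range(n) if multi_node[i]]
        nm = len(idx)
        cm = sum(correct_flags[i] for i in idx)
        report.update(
            n_multi_node=nm,
            n_multi_node_correct=int(cm),
            pct_multi_node_correct=100.0 * cm / nm if nm else 0.0,
        )
    return report
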