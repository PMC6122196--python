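# Methods

## Graph model

The reference genome is converted into a bidirected de Bruijn graph over
canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement; k odd so no k-mer is its own reverse complement). Maximal
non-branching chains are contracted into unitigs. One sequence is stored
per unitig; a signed node id (+id/−id) selects the orientation, and every
arc `(u, v)` — an exact overlap of k−1 bases between oriented sequences —
is stored together with its mirror `(−v, −u)`. Traversal code therefore
never special-cases strand, and reverse-complement reads are first-class.
Non-ACGT characters split the reference into independently processed
fragments rather than raising, since real FASTA contains N runs. Because
the graph is built from the reference itself it is complete and
error-free: every reference substring of length ≥ k spells a walk.

A sequence that contains a k-mer and its reverse complement (an inverted
repeat at k-mer scale) produces a hairpin arc between the two orientations
of one node rather than a longer unitig; this is a direct consequence of
the canonical-k-mer convention and is handled uniformly by the signed-node
machinery.

## Alignment

**Seeding.** All read k-mers are looked up in a hash index of the graph's
k-mers; hits contiguous in both read and unitig merge into one seed, and
seeds are tried longest first (cap: 10 placements; placements identical in
node and diagonal are deduplicated). Reads sharing no k-mer with the graph
fall back to maximal exact matches of length ≥ 15 (< k by construction),
found by hashed fixed-length anchors with bidirectional extension — on the
genome sizes this package targets this is equivalent to a suffix-array
scan and considerably simpler.

**Extension.** The read remainder right of the seed is aligned against
walks leaving the seed's node by a best-first branch-and-bound search.
Each search state holds a partial walk and the full Needleman–Wunsch DP
row of its spelled sequence against the remainder (linear gap model,
+1/−1/−3). The priority is the best prefix-alignment score; ties prefer
the longer consumed read prefix, then the lexicographically smaller
chain, making the search fully deterministic. A state is discarded when
`max_n(row[n] + m·(l−n)) ≤` the incumbent complete score: the maximum over
read prefixes is required for admissibility (the bound at the best prefix
alone can be exceeded by a shorter prefix with more remaining headroom).
Complete-alignment candidates (`row[l]`) are banked for every intermediate
path length, so walks that end inside a node — including the degenerate
empty extension at a dead end — are always considered. The left remainder
is extended by the same code path on the reverse-complement strand. The
search space is structurally finite: a walk stops growing once its spelled
sequence exceeds the remainder length by 16 bases (an alignment needing
more net insertions can never compete under the −3 gap penalty), which
also guarantees termination when pruning is disabled. Disabling
branch-and-bound (`--no-bb`) therefore changes visited-state counts, never
results.

A fast path covers the dominant case: when every seed places the read at
one diagonal of one unitig and the read fits inside it, the corrected
sequence is that substring and the score the ungapped comparison. The
shortcut is taken outright for ≤ 2 mismatches (where a gapped alignment
provably cannot score higher under the −3 gap penalty), verified against
the vectorized DP for 3–8 mismatches, and skipped otherwise.

**Reporting.** The corrected sequence is the spelled walk trimmed to the
read's aligned span; its score is recomputed by global DP against the
read, and identity is the fraction of matching bases in a minimum-edit
alignment. A read is reported aligned when identity ≥ 0.75 — the method
itself has no natural reporting threshold, and unaligned reads are
emitted unchanged so the output stays order- and cardinality-preserving.
A per-read budget of 10,000 search states bounds pathological repeat
regions; budget-exhausted reads return the best walk found and are
flagged in the run report.

## Two-pass Markov-model repeat resolution

Pass 1 aligns all reads unconstrained. Every aligned read's walk
contributes, for each order n ∈ [2, 10], one observation per contiguous
(n+1)-node subchain — in the walk's orientation and its mirror, so both
strands accumulate into strand-symmetric tables. Coverage c is estimated
as total aligned read bases over total unitig length (one strand), and
the model's read length l is the modal input length.

**Coverage expectation.** For a transition (state s, head v) the model
needs the expected number of reads that would *witness* it. A read's walk
contains the n+1 nodes consecutively as soon as it covers one base
exclusive to the first node, the middle nodes entirely, and one base
exclusive to the head, so the witness span M is 2 plus the spelled length
of the middle nodes — not the full spelled path, whose terminal unitigs
may be thousands of bases. (Using the full path length would drive
C_M to zero for essentially every state and silently disable the model;
the witness span makes the Poisson rate consistent with the event actually
being counted.) Then C_M = c·(l−M+1)/l, the classic start-position
argument: extending a covered span by one base keeps a uniformly-placed
read covering it with probability (l−M+1)/(l−M+2), and C_1 = c.

**Pruning and gating.** An observed transition with frequency `freq` is
discarded when `exp(C_M−1)·C_M^(−freq) ≥ 10⁵` — the ratio of Poisson
likelihoods under "the path has multiplicity zero and was observed only
through misalignment" (λ=1) versus "multiplicity at least one" (λ=C_M),
evaluated in log space. At query time orders are consulted from the
highest usable one downward; a state decides only if it is present *and*
usable (C_M ≥ 10 for the proposed transition), otherwise the next lower
order is consulted, and with no decisive order the transition is allowed.
Absence of evidence below the coverage gate is never treated as evidence
of absence.

Pass 2 re-aligns every read with the extension search skipping vetoed
transitions. Because a seed splits a read into a left and a right
extension, the right extension is redone with the left walk as history
once both sides are known, so the model sees context across the seed.
Transition probabilities are stored for inspection but only the
zero/non-zero distinction is consumed, and order-1 tables are pointless
by construction (every arc is genomic).

## Synthetic data and evaluation

The generator plants `repeat_copies` copies of one repeat (exact, or
near-identical with a per-base divergence ≤ 5%) at non-overlapping
positions, ≥ 64 bp apart so each copy has distinct flanking context, in
an i.i.d.-uniform background — the branch-and-rejoin topology whose
resolution the Markov model exists for. Read simulation emulates an
ART-style Illumina model at the level the aligner is sensitive to:
fixed-length reads, uniform starts and strands, uniform per-base
substitutions (the platform's 1–2% range) and optional uniform indels,
with an error-free twin stored per read. Position-dependent error
profiles, quality models (qualities are constant Q40) and paired-end
structure are deliberately not emulated; conclusions from these fixtures
concern the alignment machinery, not platform realism. A read counts
correctly aligned iff its corrected sequence equals its twin; unaligned
reads count only if the raw read already equals the twin. Accuracy is
additionally reported restricted to reads whose walk spans ≥ 2 nodes,
where path choice actually matters.

## Problem sizes and default study conditions

Self-checks run at desk scale, chosen so each completes in seconds to a
few minutes while still exercising every branch of the machinery:
search-optimality checks use k=7 graphs (≤ 30 unitigs) from ~200 bp
repeat-bearing references and 30–60 bp reads, solved exhaustively by an
independent enumerator; pipeline checks use a 20 kb clean genome and
50 kb genomes with four near-identical 300 bp repeat copies at 2%
divergence, 150 bp reads at 25× with 1% (clean) or 2% (repeat-stress)
substitutions. The 2% divergence gives exact shared cores of ~50 bp
between divergent sites — longer than k, shorter than the ~90 bp
usability bound implied by C_M ≥ 10 at 25× — so the guided and unguided
passes genuinely differ. The branch-and-rejoin fixture for table-recovery
tests uses a 45 bp shared core and 40 bp shared contexts for the same
reason.

## Known limitations

- The report threshold (identity 0.75), MEM floor (15), seed cap (10) and
  state budget (10,000) are engineering guards, not part of the model;
  results on pathological inputs can depend on them.
- Coverage estimation assumes most reads originate from the graphed
  genome; heavy contamination biases c and hence the gate.
- Paired-end information is ignored; each mate aligns independently.
- The two hypotheses' λ=1 misalignment rate is fixed, not adapted to the
  observed error rate.
- Execution is serial; the worker-count parameter is honored as an
  order-preservation contract, not a speedup.
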