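"""Run configuration with the package-wide parameter defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class Config:
    """All tunable parameters of the pipeline.

    Scoring defaults (+1/-1/-3), k=31, maxOrder=10, minLikelihoodRatio=1e5
    and minChainCov=10 are the method's standard settings; the remaining
    knobs (identity threshold, MEM floor, seed retry cap, state budget) are
    implementation-level guards.
    """

    k: int = 31
    match: int = 1
    mismatch: int = -1
    gap: int = -3
    max_order: int = 10
    min_likelihood_ratio: float = 1e5
    min_chain_cov: float = 10.0
    min_identity: float = 0.75
    min_mem_length: int = 15
    seed_retry_cap: int = 10
    node_visit_budget: int = 10000
    rng_seed: int = 1
    workers: int = 1
    use_bound: bool = True  # branch-and-bound pruning on/off (off: same result, slower)
    use_mm: bool = True     # two-pass Markov-model guidance on/off

    def scoring(self):
        from .extend import ScoringScheme

        return ScoringScheme(self.match, self.mismatch, self.gap)

    def to_dict(self) -> dict:
        return asdict(self)
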