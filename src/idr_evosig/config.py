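"""Run configuration and seed derivation.

One master seed lives in the config; every stochastic stage derives a child
seed from ``(master, stage name)`` so stages are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

__all__ = ["PipelineConfig", "derive_seed"]


def derive_seed(master: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (< 2**31)."""
    return zlib.crc32(f"{int(master)}:{stage}".encode()) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the region-calling and rate-filtering stages.

    Defaults are the study values: disorder regions are seeded where the
    tree-weighted average score exceeds 0.6 over at least 10 consecutive
    columns and expanded through the dilated >0.4 mask; segments shorter
    than 30 non-gap residues are dropped; rapidly evolving regions are those
    whose amino-acid or indel substitution rate exceeds 1 or 0.1.
    """

    score_high_cutoff: float = 0.6
    score_low_cutoff: float = 0.4
    dilation_size: int = 3
    seed_min_run: int = 10
    min_nongap_length: int = 30
    diversity_criteria: dict = field(
        default_factory=lambda: {"min_segments": 20, "min_clades": 2}
    )
    aa_rate_cutoff: float = 1.0
    indel_rate_cutoff: float = 0.1
    alpha_levels: tuple = (0.05, 0.01)
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.score_low_cutoff < self.score_high_cutoff <= 1.0):
            raise ValueError("need 0 <= score_low_cutoff < score_high_cutoff <= 1")
        if self.dilation_size < 1 or self.dilation_size % 2 == 0:
            raise ValueError("dilation_size must be an odd positive integer")
        if self.seed_min_run < 1 or self.min_nongap_length < 1:
            raise ValueError("seed_min_run and min_nongap_length must be positive")
        if self.aa_rate_cutoff < 0 or self.indel_rate_cutoff < 0:
            raise ValueError("rate cutoffs must be >= 0")
        for level in self.alpha_levels:
            if not 0 < level < 1:
                raise ValueError("alpha levels must be in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.rng_seed, stage)
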