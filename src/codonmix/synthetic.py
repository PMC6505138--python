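"""Synthetic genomes drawn from the two-compartment mixture.

Generation mirrors the data model end to end: a merged frequency
sequence at a known alpha (one randomized rank pairing, exactly as for
a real genome whose compartment ranks are unknown), a random assignment
of the 64 frequencies to codon labels, and multinomial count noise at
a stated total. Real codon-usage summaries are finite counts — the
10^4-codon inclusion filter only makes sense with count noise present —
so counts, not frequencies, are the generator's output. The true alpha
and the generating sequence's bias are recorded in the table metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias import bias
from .gaussian import CompartmentSequence, expected_ordered_sequence_exact, solve_mu
from .io import CODON_LABELS, N_CODONS, CodonCountTable
from .mixture import DEFAULT_SWAP_CYCLES, merge_once


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome draw."""

    alpha: float
    total_count: int = 100_000
    comp1_sigma: float = 0.009
    comp2: CompartmentSequence | None = None  # None -> packaged stand-in
    seed: int = 0
    swap_cycles: int = DEFAULT_SWAP_CYCLES
    scramble: str = "swaps"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.total_count < 1:
            raise ValueError("total_count must be >= 1")


def _resolve_compartments(spec: SyntheticGenomeSpec,
                          comp1: CompartmentSequence | None) -> tuple[CompartmentSequence, CompartmentSequence]:
    if comp1 is None:
        comp1 = expected_ordered_sequence_exact(solve_mu(spec.comp1_sigma))
    comp2 = spec.comp2
    if comp2 is None:
        from .empirical import load_packaged_strong_compartment
        comp2 = load_packaged_strong_compartment()
    return comp1, comp2


def generate_genome(spec: SyntheticGenomeSpec,
                    comp1: CompartmentSequence | None = None,
                    genome_id: str | None = None) -> CodonCountTable:
    """Draw one genome: merge, assign codon labels, sample counts."""
    comp1, comp2 = _resolve_compartments(spec, comp1)
    rng = np.random.default_rng(spec.seed)
    merged = merge_once(comp1, comp2, spec.alpha, rng,
                        swap_cycles=spec.swap_cycles, scramble=spec.scramble)
    assign = rng.permutation(N_CODONS)  # which codon label holds which rank
    probs = merged.values[assign]
    counts = rng.multinomial(spec.total_count, probs / probs.sum())
    gid = genome_id or f"synthetic-a{spec.alpha:.3f}-s{spec.seed}"
    return CodonCountTable(
        gid, f"synthetic mixture genome (alpha={spec.alpha:.3f})", counts,
        CODON_LABELS,
        metadata={"true_alpha": spec.alpha, "generating_B": bias(merged),
                  "seed": spec.seed, "total_count": spec.total_count,
                  "n_cds": 0},
    )


def generate_cohort(n: int, alpha_range: tuple[float, float] = (0.0, 1.0),
                    total_count: int = 100_000, comp1_sigma: float = 0.009,
                    comp2: CompartmentSequence | None = None, seed: int = 0,
                    swap_cycles: int = DEFAULT_SWAP_CYCLES,
                    scramble: str = "swaps",
                    id_prefix: str = "synthetic") -> list[CodonCountTable]:
    """n genomes with true alpha drawn uniformly in ``alpha_range``.

    Per-genome seeds are spawned deterministically from ``seed`` so the
    cohort is reproducible and genomes are mutually independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = alpha_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("alpha_range must be an interval within [0, 1]")
    comp1 = expected_ordered_sequence_exact(solve_mu(comp1_sigma))
    rng = np.random.default_rng(seed)
    alphas = rng.uniform(lo, hi, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [
        generate_genome(
            SyntheticGenomeSpec(alpha=float(a), total_count=total_count,
                                comp1_sigma=comp1_sigma, comp2=comp2,
                                seed=int(s), swap_cycles=swap_cycles,
                                scramble=scramble),
            comp1=comp1, genome_id=f"{id_prefix}-{k:03d}",
        )
        for k, (a, s) in enumerate(zip(alphas, seeds))
    ]
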