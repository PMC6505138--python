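"""Ordered frequency sequences and the codon-usage bias statistic B.

A genome's 64 codon frequencies, sorted in descending order, form its
frequency/rank curve. Deviation from the uniform usage 1/64 is
summarized by the root-sum-square bias

    B = sqrt( sum_i (y_i - 1/64)^2 ),

which is zero exactly for uniform usage and invariant under any
permutation of the codons. Genomes are grouped into bias histogram
bins, and the per-bin average of the members' *ordered* sequences
gives the bin's characteristic frequency/rank curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import N_CODONS, FrequencyVector

UNIFORM = 1.0 / N_CODONS


@dataclass
class OrderedFrequencySequence:
    """64 frequencies indexed by rank 1..64, non-increasing, summing to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CODONS,):
            raise ValueError(f"expected {N_CODONS} values, got shape {v.shape}")
        if (v < 0).any():
            raise ValueError("frequencies must be non-negative")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("sequence must be non-increasing in rank")
        if abs(v.sum() - 1.0) > 1e-12:
            raise ValueError(f"sequence must sum to 1 (got {v.sum()!r})")
        # no renormalization here: ordering must be idempotent bit-for-bit
        self.values = v


def _values_of(x) -> np.ndarray:
    if isinstance(x, FrequencyVector):
        return x.frequencies
    if isinstance(x, OrderedFrequencySequence):
        return x.values
    return np.asarray(x, dtype=float)


def order_descending(freq) -> OrderedFrequencySequence:
    """Sort frequencies into descending rank order (stable for ties)."""
    v = _values_of(freq)
    order = np.argsort(-v, kind="stable")
    return OrderedFrequencySequence(v[order])


def bias(freq) -> float:
    """Root-sum-square deviation of codon frequencies from uniform 1/64."""
    v = _values_of(freq)
    return float(np.sqrt(np.sum((v - UNIFORM) ** 2)))


@dataclass
class BiasHistogram:
    """Bias histogram with per-bin membership and mean ordered sequences.

    ``bin_mean_sequences[k]`` is None for empty bins; otherwise the
    arithmetic mean of the members' ordered sequences, renormalized.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_members: list[list[str]]
    bin_mean_sequences: list[OrderedFrequencySequence | None]
    out_of_range: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def bias_histogram(genomes: Iterable[tuple[str, FrequencyVector]],
                   bin_width: float = 0.005,
                   bias_range: tuple[float, float] = (0.04, 0.18)) -> BiasHistogram:
    """Histogram genomes by bias B over half-open bins [edge, edge+width).

    Genomes with B outside ``bias_range`` are listed in
    ``out_of_range`` rather than binned. The default binning (width
    0.005 over [0.04, 0.18]) spans the roughly threefold bias range
    observed across sequenced genomes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    genomes = list(genomes)
    if not genomes:
        raise ValueError("empty genome list")
    lo, hi = bias_range
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)

    members: list[list[str]] = [[] for _ in range(n_bins)]
    sums = np.zeros((n_bins, N_CODONS))
    out: list[str] = []
    for gid, fv in genomes:
        b = bias(fv)
        # epsilon guards against float error placing an exact bin-edge
        # value one bin low
        k = int(np.floor((b - lo) / bin_width + 1e-9))
        if b < lo or k >= n_bins:
            out.append(gid)
            continue
        members[k].append(gid)
        sums[k] += order_descending(fv).values

    counts = np.array([len(m) for m in members])
    mean_seqs: list[OrderedFrequencySequence | None] = []
    for k in range(n_bins):
        if counts[k] == 0:
            mean_seqs.append(None)
        else:
            m = sums[k] / counts[k]
            mean_seqs.append(OrderedFrequencySequence(m / m.sum()))
    return BiasHistogram(edges, counts, members, mean_seqs, out)


def rightmost_bin(hist: BiasHistogram) -> list[str]:
    """Genome ids in the highest-bias non-empty bin of the histogram."""
    nonempty = np.nonzero(hist.counts)[0]
    if nonempty.size == 0:
        raise ValueError("all histogram bins are empty")
    return list(hist.bin_members[int(nonempty[-1])])


def mean_ordered_sequence(seqs: Sequence[OrderedFrequencySequence]) -> OrderedFrequencySequence:
    """Arithmetic mean of ordered sequences, renormalized to sum 1."""
    if not seqs:
        raise ValueError("no sequences to average")
    m = np.mean([s.values for s in seqs], axis=0)
    return OrderedFrequencySequence(m / m.sum())
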