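"""Schematic plots: frequency/rank curves and the alpha-vs-B relation."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gaussian import N_CODONS, UNIFORM
from .mixture import theoretical_B

RANKS = np.arange(1, N_CODONS + 1)


def plot_frequency_rank(sequences, labels=None, ax=None):
    """Overlay ordered frequency/rank curves (one line per genome)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = labels or [None] * len(sequences)
    for seq, lab in zip(sequences, labels):
        vals = getattr(seq, "values", seq)
        ax.plot(RANKS, vals, lw=1, label=lab)
    ax.axhline(UNIFORM, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("rank")
    ax.set_ylabel("codon frequency")
    if any(l is not None for l in labels):
        ax.legend(fontsize=7)
    return ax


def plot_fit(result, ax=None):
    """Observed vs fitted theoretical curve, residuals along the bottom."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(RANKS, result.model.observed.values if result.model else
                    result.theoretical_sequence.values + result.residuals,
                    color="0.8", label="observed")
    ax.plot(RANKS, result.theoretical_sequence.values, "k-", lw=1,
            label=f"model (alpha={result.alpha_hat:.2f})")
    ax.plot(RANKS, result.residuals, ":", c="tab:red", lw=1, label="residual")
    ax.axhline(0, c="gray", lw=0.5)
    ax.set_xlabel("rank")
    ax.set_ylabel("codon frequency")
    ax.legend(fontsize=7)
    return ax


def plot_alpha_vs_bias(alphas, biases, s1, s2, ax=None):
    """Fitted alpha against observed B, with the closed-form relation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(biases, alphas, "o", ms=3, alpha=0.6, label="genomes")
    a_grid = np.linspace(0, 1, 201)
    ax.plot([theoretical_B(a, s1, s2) for a in a_grid], a_grid, "-", c="k",
            lw=1, label="variance composition")
    ax.set_xlabel("observed bias B")
    ax.set_ylabel("fitted alpha")
    ax.legend(fontsize=7)
    return ax
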