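"""The strong-bias compartment, described empirically.

Unlike the weak-bias compartment, no parametric family is imposed on
strongly biased codon usage: the compartment's expected ordered
sequence is simply the average of the ordered frequency sequences of
the genomes in the highest-bias bin of the bias histogram. It is
treated as a tabulated input from then on.

A synthetic stand-in ships with the package so the full pipeline runs
without any external codon-usage database: a smooth exponential decay
over ranks, rescaled to mean 1/64 with the decay constant solved so
the standard deviation about the mean equals 0.0207 — the two
statistics the bias-composition relation uses — while keeping the
qualitative cascade-like shape of real strong-bias sequences.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .bias import BiasHistogram, FrequencyVector, order_descending, rightmost_bin
from .gaussian import N_CODONS, UNIFORM, CompartmentSequence

STRONG_SD_DEFAULT = 0.0207


def derive_empirical(genomes: Iterable[tuple[str, FrequencyVector]],
                     hist: BiasHistogram) -> CompartmentSequence:
    """Average the ordered sequences of the highest-bias-bin genomes.

    The result is renormalized to sum 1 (mean exactly 1/64); its sd is
    the s2 entering the bias-composition relation.
    """
    genomes = list(genomes)
    ids = [gid for gid, _ in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids; membership matching would be ambiguous")
    members = set(rightmost_bin(hist))
    seqs = [order_descending(fv).values for gid, fv in genomes if gid in members]
    if not seqs:
        raise ValueError("no genomes found in the right-most histogram bin")
    m = np.mean(seqs, axis=0)
    return CompartmentSequence(m / m.sum(), source="empirical", sum_tolerance=1e-9,
                               meta={"n_genomes": len(seqs)})


def save_compartment(seq: CompartmentSequence, path) -> None:
    """Write a compartment sequence as TSV (rank, frequency), full precision."""
    with open(path, "w") as fh:
        fh.write(f"# source: {seq.source}\n")
        fh.write("rank\tfrequency\n")
        for rank, v in enumerate(seq.values, start=1):
            fh.write(f"{rank}\t{float(v)!r}\n")


def load_compartment(path, source: str | None = None) -> CompartmentSequence:
    """Read a compartment sequence written by :func:`save_compartment`."""
    path = Path(path)
    tag = source
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if tag is None and line.startswith("# source:"):
                tag = line.split(":", 1)[1].strip()
            continue
        if line.startswith("rank"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: malformed row {line!r}")
        values.append(float(fields[1]))
    if len(values) != N_CODONS:
        raise ValueError(f"{path}: expected {N_CODONS} rows, got {len(values)}")
    return CompartmentSequence(np.array(values), source=tag or "empirical",
                               sum_tolerance=1e-9)


def synthetic_strong_compartment(sd: float = STRONG_SD_DEFAULT) -> CompartmentSequence:
    """Construct the synthetic stand-in for the strong-bias compartment.

    Frequencies decay exponentially with rank, v_k proportional to
    exp(-(k-1)/tau), normalized to sum 1; tau is root-solved so the
    sample sd about 1/64 (denominator 63) equals ``sd`` exactly.
    """
    ranks = np.arange(N_CODONS, dtype=float)

    def sd_of(tau: float) -> float:
        v = np.exp(-ranks / tau)
        v /= v.sum()
        return float(np.sqrt(np.sum((v - UNIFORM) ** 2) / (N_CODONS - 1)))

    if not sd_of(1.0) > sd > sd_of(5000.0):
        raise ValueError(f"target sd {sd} outside the attainable range")
    tau = brentq(lambda t: sd_of(t) - sd, 1.0, 5000.0, xtol=1e-12)
    v = np.exp(-ranks / tau)
    return CompartmentSequence(v / v.sum(), source="synthetic", sum_tolerance=1e-9,
                               meta={"tau": tau, "target_sd": sd})


def load_packaged_strong_compartment() -> CompartmentSequence:
    """Load the packaged synthetic strong-bias stand-in (sd = 0.0207)."""
    ref = resources.files("codonmix.data").joinpath("strong_compartment_synthetic.tsv")
    with resources.as_file(ref) as p:
        return load_compartment(p)
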