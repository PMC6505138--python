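"""Reading, writing and validating genomic codon-count data.

Codon usage summaries come in three dialects:

* the CUTG ``.spsum`` dialect: two lines per genome, a colon-separated
  header (``id:species:cds_count``) followed by 64 whitespace-separated
  integer codon counts in the database's fixed column order;
* a generic TSV with columns ``genome_id``, ``species`` and 64 codon
  count columns;
* FASTA coding sequences, counted into codon tables on the fly.

The column order of spsum files is defined by the CUTG companion label
file, not by the counts themselves; the shipped label table can be
overridden per call. All downstream analysis sorts frequencies, so
results do not depend on the label order — labels matter for reporting
only. Labels are stored as given and compared case-insensitively with
T equivalent to U. All 64 codons participate, stop codons included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

N_CODONS = 64

_VALID_BASES = frozenset("ACGTU")


class SpsumParseError(ValueError):
    """Raised when an spsum or TSV codon file violates the dialect."""


def _load_packaged_labels() -> tuple[str, ...]:
    text = resources.files("codonmix.data").joinpath("spsum_labels.txt").read_text()
    labels = tuple(text.split())
    if len(labels) != N_CODONS:
        raise RuntimeError("packaged codon label table is corrupt")
    return labels


#: Fixed spsum column order (RNA alphabet), loaded from the packaged table.
CODON_LABELS: tuple[str, ...] = _load_packaged_labels()


def normalize_codon(codon: str) -> str:
    """Canonical form for codon comparison: uppercase, U mapped to T."""
    return codon.upper().replace("U", "T")


def _validate_labels(labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(labels)
    if len(labels) != N_CODONS:
        raise ValueError(f"expected {N_CODONS} codon labels, got {len(labels)}")
    norm = [normalize_codon(c) for c in labels]
    if len(set(norm)) != N_CODONS:
        raise ValueError("codon labels are not unique (T/U-insensitive)")
    for c in labels:
        if len(c) != 3 or not set(c.upper()) <= _VALID_BASES:
            raise ValueError(f"invalid codon label {c!r}")
    return labels


@dataclass
class CodonCountTable:
    """One genome's 64 codon counts with identity labels.

    Parameters
    ----------
    genome_id : str
        Identifier (CUTG uses a taxon id).
    species : str
        Species / organism name.
    counts : array of int, shape (64,)
        Non-negative occurrence counts, one per distinct codon.
    codon_labels : sequence of str
        64 unique trinucleotide labels over {A,C,G,T/U}.
    metadata : dict
        Free-form provenance (e.g. ``true_alpha`` for synthetic genomes,
        ``skipped_codons`` for FASTA-derived tables).
    """

    genome_id: str
    species: str
    counts: np.ndarray
    codon_labels: tuple[str, ...] = CODON_LABELS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CODONS,):
            raise ValueError(f"expected {N_CODONS} counts, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("codon counts must be non-negative")
        self.codon_labels = _validate_labels(self.codon_labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frequencies(self) -> "FrequencyVector":
        return to_frequencies(self)


@dataclass
class FrequencyVector:
    """64 codon frequencies y_i = c_i / Σc, summing to exactly 1."""

    frequencies: np.ndarray
    codon_labels: tuple[str, ...] = CODON_LABELS

    def __post_init__(self) -> None:
        y = np.asarray(self.frequencies, dtype=float)
        if y.shape != (N_CODONS,):
            raise ValueError(f"expected {N_CODONS} frequencies, got shape {y.shape}")
        if (y < 0).any():
            raise ValueError("frequencies must be non-negative")
        s = y.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"frequencies must sum to 1 (got {s!r})")
        self.frequencies = y / s
        self.codon_labels = _validate_labels(self.codon_labels)


def to_frequencies(table: CodonCountTable) -> FrequencyVector:
    """Normalize a count table to a frequency vector.

    Raises ``ValueError`` for an all-zero table, which cannot be
    normalized (such tables are legal as parsed input and are meant to
    be removed by :func:`filter_by_total`).
    """
    total = table.counts.sum()
    if total <= 0:
        raise ValueError(f"genome {table.genome_id!r}: zero total count, cannot normalize")
    y = table.counts / total
    return FrequencyVector(y / y.sum(), table.codon_labels)


def read_spsum(path, labels: Sequence[str] | None = None) -> list[CodonCountTable]:
    """Parse a CUTG-dialect ``.spsum`` file.

    The file alternates header lines (``id:species:cds_count``; the
    species name may itself contain colons, so the first field is the
    id and the last is the CDS count) with count lines of 64
    whitespace-separated integers.
    """
    labels = _validate_labels(labels) if labels is not None else CODON_LABELS
    path = Path(path)
    lines = path.read_text().splitlines()
    # drop trailing blank lines, keep interior structure strict
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 2 != 0:
        raise SpsumParseError(f"{path}: odd number of non-empty lines; expected header/count pairs")
    tables = []
    for k in range(0, len(lines), 2):
        header, countline = lines[k], lines[k + 1]
        parts = header.split(":")
        if len(parts) < 2:
            raise SpsumParseError(f"{path}, line {k + 1}: malformed header {header!r}")
        genome_id = parts[0].strip()
        try:
            n_cds = int(parts[-1])
        except ValueError as exc:
            raise SpsumParseError(
                f"{path}, line {k + 1}: CDS count field is not an integer in {header!r}"
            ) from exc
        species = ":".join(parts[1:-1]).strip()
        fields = countline.split()
        if len(fields) != N_CODONS:
            raise SpsumParseError(
                f"{path}, line {k + 2}: expected {N_CODONS} counts, got {len(fields)}"
            )
        try:
            counts = np.array([int(f) for f in fields], dtype=np.int64)
        except ValueError as exc:
            raise SpsumParseError(f"{path}, line {k + 2}: non-integer count field") from exc
        if (counts < 0).any():
            raise SpsumParseError(f"{path}, line {k + 2}: negative codon count")
        tables.append(
            CodonCountTable(genome_id, species, counts, labels, metadata={"n_cds": n_cds})
        )
    return tables


def write_spsum(tables: Sequence[CodonCountTable], path) -> None:
    """Write tables in the spsum dialect (inverse of :func:`read_spsum`)."""
    with open(path, "w") as fh:
        for t in tables:
            n_cds = t.metadata.get("n_cds", 0)
            fh.write(f"{t.genome_id}:{t.species}:{n_cds}\n")
            fh.write(" ".join(str(int(c)) for c in t.counts) + "\n")


def read_counts_tsv(path) -> list[CodonCountTable]:
    """Read the generic TSV dialect: genome_id, species, 64 codon columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"genome_id": str, "species": str})
    codon_cols = [c for c in df.columns if c not in ("genome_id", "species")]
    if len(codon_cols) != N_CODONS:
        raise SpsumParseError(f"{path}: expected {N_CODONS} codon columns, got {len(codon_cols)}")
    labels = _validate_labels(codon_cols)
    return [
        CodonCountTable(str(row["genome_id"]), str(row["species"]),
                        row[list(codon_cols)].to_numpy(dtype=np.int64), labels)
        for _, row in df.iterrows()
    ]


def write_frequencies_tsv(tables: Sequence[CodonCountTable], path) -> None:
    """Write normalized frequencies in the generic TSV dialect."""
    rows = []
    for t in tables:
        fv = to_frequencies(t)
        rows.append({"genome_id": t.genome_id, "species": t.species,
                     **dict(zip(t.codon_labels, fv.frequencies))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def count_codons_fasta(path, frame_offset: int = 0,
                       labels: Sequence[str] | None = None) -> list[CodonCountTable]:
    """Count codons in FASTA coding sequences, one table per record.

    Reads non-overlapping triplets starting at ``frame_offset``; the
    trailing partial codon and any triplet containing a character
    outside {A,C,G,T,U} are skipped and tallied in
    ``metadata['skipped_codons']``.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    labels = _validate_labels(labels) if labels is not None else CODON_LABELS
    index = {normalize_codon(c): i for i, c in enumerate(labels)}
    tables = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        counts = np.zeros(N_CODONS, dtype=np.int64)
        skipped = 0
        if len(seq) - frame_offset < 3:
            logger.warning("record %s: sequence shorter than one codon", rec.id)
        for i in range(frame_offset, len(seq) - 2, 3):
            codon = normalize_codon(seq[i:i + 3])
            j = index.get(codon)
            if j is None:
                skipped += 1
            else:
                counts[j] += 1
        tables.append(CodonCountTable(rec.id, rec.description, counts, labels,
                                      metadata={"skipped_codons": skipped}))
    if not tables:
        raise ValueError(f"{path}: no FASTA records found")
    return tables


def filter_by_total(tables: Sequence[CodonCountTable], min_total: int = 10_000) -> list[CodonCountTable]:
    """Retain genomes with total codon count >= ``min_total`` (order kept).

    The default threshold of 10^4 codons keeps only genomes whose
    frequency estimates carry per-codon sampling noise well below the
    structure the mixture model fits.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    return [t for t in tables if t.total >= min_total]
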