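"""Amino-acid conservation from alignment columns, mapped to nucleotides.

For each codon of a protein-coding gene, the Shannon entropy of the
corresponding alignment column,

    S = -sum_i p_i ln p_i,

measures amino-acid variability across species (p_i is the fraction of
sequences showing residue type i).  The conservation score C = 2 exp(-S)
equals 2 for a completely conserved column and decays toward zero as the
column diversifies; an alternative convention C = 2^(-S) is available.  Each
codon's score is broadcast onto its three nucleotide positions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignmentColumn",
    "ConservationTrack",
    "alignment_columns",
    "column_entropy",
    "conservation_score",
    "codon_of_position",
    "codon_span",
    "map_codon_conservation",
    "conservation_track",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class AlignmentColumn:
    """Residue counts at one alignment position.

    Gaps are excluded from the counts by default; with
    ``gaps="as-residue"`` the gap character is kept as a 21st symbol.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("residue counts must be non-negative")
        if self.total < 2:
            raise ValueError("alignment column needs at least 2 residues")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {aa: c / t for aa, c in self.counts.items() if c > 0}

    @classmethod
    def from_residues(cls, residues: Iterable[str], gaps: str = "exclude") -> "AlignmentColumn":
        if gaps not in ("exclude", "as-residue"):
            raise ValueError(f"unknown gap policy {gaps!r}")
        res = [r.upper() for r in residues]
        if gaps == "exclude":
            res = [r for r in res if r not in GAP_CHARS]
        return cls(counts=dict(Counter(res)))


def alignment_columns(sequences: Sequence[str], gaps: str = "exclude") -> list[AlignmentColumn]:
    """Columns of an alignment given as equal-length residue strings."""
    if len(sequences) < 2:
        raise ValueError("an alignment needs at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    return [
        AlignmentColumn.from_residues(col, gaps=gaps) for col in zip(*sequences)
    ]


def column_entropy(col: AlignmentColumn) -> float:
    """Shannon entropy S = -sum p_i ln p_i (nats) of one column."""
    return float(-sum(p * math.log(p) for p in col.fractions.values()))


def conservation_score(S: float, base: str = "e") -> float:
    """Conservation C from entropy S.

    The default convention is C = 2 exp(-S), which equals 2 at S = 0
    (complete conservation) and separates conserved from variable columns
    more sharply than the alternative C = 2^(-S) selected by ``base="2"``.
    """
    if S < 0:
        raise ValueError(f"entropy must be non-negative, got {S}")
    if base == "e":
        return 2.0 * math.exp(-S)
    if base == "2":
        return 2.0 ** (-S)
    raise ValueError(f"unknown base {base!r}")


def codon_of_position(position: int, gene_start: int) -> int:
    """1-based codon index covering a nucleotide position."""
    if position < gene_start:
        raise ValueError(f"position {position} precedes gene start {gene_start}")
    return (position - gene_start) // 3 + 1


def codon_span(codon: int, gene_start: int) -> tuple[int, int]:
    """Nucleotide interval [start, end] (1-based inclusive) of a codon."""
    if codon < 1:
        raise ValueError("codon index is 1-based")
    lo = gene_start + 3 * (codon - 1)
    return lo, lo + 2


@dataclass(frozen=True)
class ConservationTrack:
    """Per-codon entropy and conservation anchored to a gene interval."""

    S: np.ndarray
    C: np.ndarray
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if (self.gene_end - self.gene_start + 1) != 3 * len(self.S):
            raise ValueError("gene span does not cover the codons")

    @property
    def n_codons(self) -> int:
        return len(self.S)

    def per_nucleotide(self) -> np.ndarray:
        """Conservation per nucleotide of [gene_start, gene_end]."""
        return np.repeat(self.C, 3)


def map_codon_conservation(
    per_codon: np.ndarray, gene_start: int, gene_end: int
) -> np.ndarray:
    """Broadcast per-codon values onto nucleotide coordinates.

    Codon k covers gene_start + 3(k-1) .. gene_start + 3k - 1; the gene span
    must be a whole number of codons matching ``per_codon``.
    """
    span = gene_end - gene_start + 1
    if span % 3 != 0:
        raise ValueError(f"gene span {gene_start}-{gene_end} is not a multiple of 3")
    if span != 3 * len(per_codon):
        raise ValueError(
            f"{len(per_codon)} codon values cannot tile {span} nucleotides"
        )
    return np.repeat(np.asarray(per_codon, dtype=float), 3)


def conservation_track(
    sequences: Sequence[str],
    gene_start: int,
    gene_end: int,
    gaps: str = "exclude",
    base: str = "e",
) -> ConservationTrack:
    """Entropy and conservation per codon from an amino-acid alignment.

    The alignment must have one column per codon of [gene_start, gene_end].
    """
    cols = alignment_columns(sequences, gaps=gaps)
    span = gene_end - gene_start + 1
    if span != 3 * len(cols):
        raise ValueError(
            f"alignment has {len(cols)} columns but {gene_start}-{gene_end} "
            f"spans {span} nt ({span / 3:.1f} codons)"
        )
    S = np.array([column_entropy(c) for c in cols])
    C = np.array([conservation_score(s, base=base) for s in S])
    return ConservationTrack(S=S, C=C, gene_start=gene_start, gene_end=gene_end)
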