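"""Two-legged tight-binding ladder model of a DNA duplex.

A duplex is modelled as two parallel chains of lattice sites, one per
strand, with one site per base.  A hole (missing electron) hops between
stacked neighbours on the same strand with amplitude ``t_par`` and across
each Watson-Crick rung with amplitude ``t_perp``; its on-site energy is the
ionization potential of the base occupying the site.  Guanine, having the
lowest ionization potential, acts as the deepest potential well and is the
preferred localization site.

Coordinates are 1-based and inclusive throughout (mtDNA rCRS convention);
the reference strand is labelled ``L`` and its complement ``H``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPLEMENT",
    "BaseSequence",
    "LadderDuplex",
    "ModelParams",
    "HoleHamiltonian",
    "complement_strand",
    "build_duplex",
    "build_hamiltonian",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

#: minimum ladder length: with periodic boundaries a 2-site ring would place
#: two bonds between the same pair of sites
MIN_SITES = 3


@dataclass(frozen=True)
class BaseSequence:
    """A single strand of DNA with genomic coordinates.

    Parameters
    ----------
    bases : str
        Sequence over the alphabet ``ACGT`` (``N`` allowed only with
        ``allow_ambiguous=True``; see `ModelParams.ambiguous`).
    start : int
        1-based genomic coordinate of the first base.
    strand : {"L", "H"}
        Strand label; ``L`` is the reference strand.
    """

    bases: str
    start: int = 1
    strand: str = "L"
    allow_ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", str(self.bases).upper())
        if len(self.bases) < MIN_SITES:
            raise ValueError(
                f"sequence must have at least {MIN_SITES} bases, got {len(self.bases)}"
            )
        if self.start < 1:
            raise ValueError(f"start coordinate must be >= 1, got {self.start}")
        if self.strand not in ("L", "H"):
            raise ValueError(f"strand must be 'L' or 'H', got {self.strand!r}")
        alphabet = set("ACGTN") if self.allow_ambiguous else set("ACGT")
        for i, b in enumerate(self.bases):
            if b not in alphabet:
                raise ValueError(
                    f"invalid base {b!r} at position {i + 1} "
                    f"(genomic coordinate {self.start + i})"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """1-based inclusive coordinate of the last base."""
        return self.start + len(self.bases) - 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def subsequence(self, start: int, end: int) -> "BaseSequence":
        """Closed-interval extraction ``[start, end]`` in genomic coordinates."""
        if not (self.start <= start <= end <= self.end):
            raise ValueError(
                f"range {start}-{end} outside sequence span {self.start}-{self.end}"
            )
        i, j = start - self.start, end - self.start + 1
        return BaseSequence(self.bases[i:j], start=start, strand=self.strand,
                            allow_ambiguous=self.allow_ambiguous)


def complement_strand(seq: BaseSequence) -> BaseSequence:
    """Watson-Crick complement on identical coordinates (not reversed).

    The ladder aligns the two chains position-by-position, so the complement
    keeps the same genomic coordinates and direction.
    """
    comp = "".join(COMPLEMENT[b] for b in seq.bases)
    other = "H" if seq.strand == "L" else "L"
    return BaseSequence(comp, start=seq.start, strand=other,
                        allow_ambiguous=seq.allow_ambiguous)


@dataclass(frozen=True)
class LadderDuplex:
    """Two complementary chains aligned position-by-position."""

    l_chain: BaseSequence
    h_chain: BaseSequence

    def __post_init__(self) -> None:
        if len(self.l_chain) != len(self.h_chain):
            raise ValueError("chains differ in length")
        if self.l_chain.start != self.h_chain.start:
            raise ValueError("chains differ in coordinates")
        for i, (a, b) in enumerate(zip(self.l_chain.bases, self.h_chain.bases)):
            if COMPLEMENT[a] != b:
                raise ValueError(
                    f"non-complementary pair {a}/{b} at genomic coordinate "
                    f"{self.l_chain.start + i}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.l_chain)

    @property
    def start(self) -> int:
        return self.l_chain.start

    @property
    def end(self) -> int:
        return self.l_chain.end


def build_duplex(l_strand: BaseSequence) -> LadderDuplex:
    """Build the ladder duplex from the reference (L) strand."""
    if l_strand.strand != "L":
        raise ValueError("build_duplex expects the reference (L) strand")
    return LadderDuplex(l_chain=l_strand, h_chain=complement_strand(l_strand))


@dataclass(frozen=True)
class ModelParams:
    """Tight-binding parameters (all energies in eV).

    Defaults are gas-phase ionization potentials of the four bases and the
    standard ladder hopping amplitudes: ``t_par`` couples stacked neighbours
    along a strand, ``t_perp`` couples the two bases of a pair.  ``periodic``
    joins the first and last site of each chain, matching the circular
    topology of mtDNA on the analysed segment.

    ``ambiguous`` controls sites whose base is ``N``: ``"reject"`` (default)
    refuses to build a Hamiltonian, ``"impute-mean"`` assigns the average of
    the four on-site energies.
    """

    eps_g: float = 7.75
    eps_c: float = 8.87
    eps_a: float = 8.24
    eps_t: float = 9.14
    t_par: float = 1.0
    t_perp: float = 0.5
    periodic: bool = True
    ambiguous: str = "reject"

    def __post_init__(self) -> None:
        for name in ("eps_g", "eps_c", "eps_a", "eps_t", "t_par", "t_perp"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.t_par < 0 or self.t_perp < 0:
            raise ValueError("hopping amplitudes must be non-negative")
        if self.ambiguous not in ("reject", "impute-mean"):
            raise ValueError(f"unknown ambiguous-base policy {self.ambiguous!r}")

    def on_site(self, base: str) -> float:
        """On-site hole energy for one base."""
        table = {"G": self.eps_g, "C": self.eps_c, "A": self.eps_a, "T": self.eps_t}
        if base in table:
            return table[base]
        if base == "N":
            if self.ambiguous == "impute-mean":
                return (self.eps_g + self.eps_c + self.eps_a + self.eps_t) / 4.0
            raise ValueError(
                "ambiguous base 'N' encountered (policy 'reject'; "
                "use ambiguous='impute-mean' to assign the mean on-site energy)"
            )
        raise ValueError(f"unknown base {base!r}")


@dataclass(frozen=True)
class HoleHamiltonian:
    """Real symmetric 2N x 2N single-hole Hamiltonian.

    Basis ordering is by blocks: sites 0..N-1 are the L chain, N..2N-1 the
    H chain, so strand-wise marginals are contiguous slices.
    """

    matrix: np.ndarray
    duplex: LadderDuplex
    params: ModelParams

    @property
    def n_sites(self) -> int:
        return self.duplex.n_sites

    @property
    def dimension(self) -> int:
        return 2 * self.n_sites

    def index(self, site: int, chain: int) -> int:
        """Matrix row for 0-based ``site`` on ``chain`` (0 = L, 1 = H)."""
        n = self.n_sites
        if not (0 <= site < n) or chain not in (0, 1):
            raise IndexError(f"no site ({site}, chain {chain}) in a {n}-pair ladder")
        return site + chain * n


def build_hamiltonian(duplex: LadderDuplex, params: ModelParams | None = None) -> HoleHamiltonian:
    """Assemble the tight-binding matrix for a duplex.

    Diagonal entries are on-site energies by base identity; off-diagonal
    entries are ``t_par`` between chain neighbours (plus the wrap-around bond
    of each chain when periodic) and ``t_perp`` across each rung.
    """
    params = params or ModelParams()
    n = duplex.n_sites
    h = np.zeros((2 * n, 2 * n))
    for i, b in enumerate(duplex.l_chain.bases):
        h[i, i] = params.on_site(b)
    for i, b in enumerate(duplex.h_chain.bases):
        h[n + i, n + i] = params.on_site(b)
    for off in (0, n):  # intra-chain bonds, one block per strand
        for i in range(n - 1):
            h[off + i, off + i + 1] = h[off + i + 1, off + i] = params.t_par
        if params.periodic:
            h[off, off + n - 1] = h[off + n - 1, off] = params.t_par
    for i in range(n):  # rungs
        h[i, n + i] = h[n + i, i] = params.t_perp
    return HoleHamiltonian(matrix=h, duplex=duplex, params=params)
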