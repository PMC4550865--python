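"""Seeded generators for sequences, variant tracks, and toy alignments.

These emulate the inputs of the full pipeline without any downloads: DNA
segments with guanine runs planted in a uniform or random background
(mimicking the G-triplet/quadruplet hole traps of natural sequence),
variant-frequency tracks with spikes at chosen positions plus optional
Poisson background noise, and amino-acid alignment columns drawn from
specified residue distributions.  Every stochastic generator requires an
explicit seed and is a pure function of its arguments; NumPy's PCG64
default generator keeps the draws bit-reproducible across platforms.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .ladder import BaseSequence
from .variants import VariantTrack

__all__ = ["make_planted_sequence", "make_variant_track", "make_alignment"]

_DNA = np.array(list("ACGT"))


def make_planted_sequence(
    length: int,
    background: str = "A",
    motifs: Sequence[tuple[int, str, int]] = (),
    gc: float | None = None,
    seed: int | None = None,
    start: int = 1,
) -> BaseSequence:
    """A background sequence with base runs planted at exact positions.

    Parameters
    ----------
    length : int
        Number of bases.
    background : str
        Single base used as the uniform background (ignored in random mode).
    motifs : sequence of (position, base, run_length)
        Runs to plant; ``position`` is the 1-based coordinate (on the same
        scale as ``start``) of the first base of the run.  Motifs must lie
        within bounds and must not overlap.
    gc : float, optional
        If given, the background is instead random with this G+C content
        (AT and GC split evenly within their classes); requires ``seed``.
    seed : int, optional
        Mandatory for the random mode.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    if gc is not None:
        if not (0 <= gc <= 1):
            raise ValueError("gc must lie in [0, 1]")
        if seed is None:
            raise ValueError("random mode requires a seed")
        rng = np.random.default_rng(seed)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
        bases = rng.choice(_DNA, size=length, p=probs)
    else:
        if background not in "ACGT" or len(background) != 1:
            raise ValueError(f"background must be one base, got {background!r}")
        bases = np.full(length, background)
    occupied = np.zeros(length, dtype=bool)
    for pos, base, run in motifs:
        if base not in "ACGT":
            raise ValueError(f"motif base must be in ACGT, got {base!r}")
        if run < 1:
            raise ValueError("motif run length must be >= 1")
        i = pos - start
        if i < 0 or i + run > length:
            raise ValueError(f"motif at {pos} (run {run}) out of bounds")
        if occupied[i : i + run].any():
            raise ValueError(f"motif at {pos} overlaps a previous motif")
        occupied[i : i + run] = True
        bases[i : i + run] = base
    return BaseSequence("".join(bases), start=start, strand="L")


def make_variant_track(
    length: int,
    spikes: Sequence[tuple[int, float]] = (),
    noise_lambda: float = 0.0,
    seed: int | None = None,
    start: int = 1,
) -> VariantTrack:
    """A zero (or Poisson-noise) background with frequency spikes.

    ``spikes`` are (position, magnitude) pairs on the ``start`` coordinate
    scale; magnitudes add to the background.  ``noise_lambda > 0`` draws
    i.i.d. Poisson counts per position and requires a seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if noise_lambda < 0:
        raise ValueError("noise_lambda must be >= 0")
    if noise_lambda > 0:
        if seed is None:
            raise ValueError("Poisson noise requires a seed")
        g = np.random.default_rng(seed).poisson(noise_lambda, size=length).astype(float)
    else:
        g = np.zeros(length)
    for pos, mag in spikes:
        if mag < 0:
            raise ValueError(f"spike magnitude at {pos} is negative")
        i = pos - start
        if not (0 <= i < length):
            raise ValueError(f"spike position {pos} out of bounds")
        g[i] += mag
    return VariantTrack(g=g, start=start)


def make_alignment(
    columns: Sequence[Mapping[str, float]],
    depth: int,
    seed: int,
) -> list[str]:
    """Aligned residue rows drawn column-wise from categorical distributions.

    ``columns[k]`` maps residue -> probability for alignment column k; each
    distribution must sum to one.  Returns ``depth`` strings of equal
    length, one per aligned sequence.
    """
    if depth < 2:
        raise ValueError("alignment depth must be >= 2")
    rng = np.random.default_rng(seed)
    cols = []
    for k, dist in enumerate(columns):
        residues = sorted(dist)
        p = np.array([dist[r] for r in residues], dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"column {k}: probabilities must be >= 0 and sum to 1")
        cols.append(rng.choice(np.array(residues), size=depth, p=p / p.sum()))
    return ["".join(row) for row in zip(*cols)]
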