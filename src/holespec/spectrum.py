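"""Eigenstates, Boltzmann-weighted hole spectra, and normalized tracks.

Diagonalizing the ladder Hamiltonian gives 2N orthonormal eigenstates.  The
hole spectrum is the canonical-ensemble average of the per-site densities,

    P(m, c) = sum_i w_i |Psi_i(m, c)|^2,
    w_i = exp(-(E_i - E_0) / kBT) / Z,

where E_0 is the ground-state energy and kBT an effective (pseudo-thermal)
energy, by default 0.047 eV.  P sums to one over all sites of both strands.
Normalized tracks divide P by a baseline mean: over all 2N sites (so a
uniform duplex sits at N = 1 hole per base), or over one strand alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .ladder import HoleHamiltonian

__all__ = [
    "EigenSystem",
    "HoleSpectrum",
    "NormalizedTrack",
    "diagonalize",
    "boltzmann_weights",
    "hole_spectrum",
    "normalize_track",
    "DEFAULT_KBT",
]

DEFAULT_KBT = 0.047  # eV, effective pseudo-thermal energy

_STRAND_INDEX = {"L": 0, "H": 1}


@dataclass(frozen=True)
class EigenSystem:
    """Full real spectrum of a ladder Hamiltonian.

    ``densities[i, m, c]`` is |Psi_i(m, c)|^2 for eigenstate i, 0-based site
    m and chain c (0 = L, 1 = H); energies are sorted ascending.
    """

    energies: np.ndarray
    densities: np.ndarray
    start: int
    periodic: bool

    @property
    def n_states(self) -> int:
        return len(self.energies)

    @property
    def n_sites(self) -> int:
        return self.densities.shape[1]

    @property
    def ground_energy(self) -> float:
        return float(self.energies[0])


def diagonalize(ham: HoleHamiltonian, atol: float = 1e-12) -> EigenSystem:
    """Dense symmetric eigensolve, re-indexed to (site, chain).

    Rejects non-symmetric input rather than silently symmetrizing.
    """
    m = ham.matrix
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("Hamiltonian matrix is not symmetric")
    energies, vectors = scipy.linalg.eigh(m)
    n = ham.n_sites
    dens = (vectors.T ** 2).reshape(2 * n, 2, n).transpose(0, 2, 1)
    # reshape above relies on block basis ordering (L sites then H sites)
    return EigenSystem(
        energies=energies,
        densities=dens,
        start=ham.duplex.start,
        periodic=ham.params.periodic,
    )


def boltzmann_weights(es: EigenSystem, kBT: float = DEFAULT_KBT) -> np.ndarray:
    """Canonical occupation weights w_i, normalized to sum to one."""
    if kBT <= 0:
        raise ValueError(f"kBT must be positive, got {kBT}")
    w = np.exp(-(es.energies - es.ground_energy) / kBT)
    return w / w.sum()


@dataclass(frozen=True)
class HoleSpectrum:
    """Per-position, per-strand hole probability.

    ``P[m, c]`` sums to one over both strands; ``start`` anchors 0-based
    site m to the genomic coordinate ``start + m``.
    """

    P: np.ndarray
    kBT: float
    start: int
    periodic: bool
    weights: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.P.shape[0]

    @property
    def end(self) -> int:
        return self.start + self.n_sites - 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def strand(self, strand: str) -> np.ndarray:
        return self.P[:, _STRAND_INDEX[strand]]


def hole_spectrum(es: EigenSystem, kBT: float = DEFAULT_KBT) -> HoleSpectrum:
    """Boltzmann-average the eigenstate densities into a hole spectrum."""
    w = boltzmann_weights(es, kBT)
    p = np.tensordot(w, es.densities, axes=(0, 0))
    # eigenvector round-off can leave probabilities at -1e-16; clamp
    p[(p < 0) & (p > -1e-14)] = 0.0
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise RuntimeError(f"hole probabilities sum to {total}, expected 1")
    return HoleSpectrum(P=p, kBT=kBT, start=es.start, periodic=es.periodic, weights=w)


@dataclass(frozen=True)
class NormalizedTrack:
    """Dimensionless hole heights N = P / baseline.

    mode ``both_strands`` uses the mean of P over all 2N sites (analytically
    1/(2N)); ``L_only`` / ``H_only`` use the mean over that strand's sites,
    so the mean of N over the baseline-defining positions is one.
    """

    values: np.ndarray
    mode: str
    baseline: float
    start: int
    periodic: bool

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def end(self) -> int:
        return self.start + self.n_sites - 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def strand(self, strand: str) -> np.ndarray:
        return self.values[:, _STRAND_INDEX[strand]]


def normalize_track(spec: HoleSpectrum, mode: str = "both_strands") -> NormalizedTrack:
    """Divide the spectrum by the chosen baseline average.

    For ``both_strands`` the computed baseline doubles as a self-check
    against the analytic value 1/(2N).
    """
    if mode == "both_strands":
        baseline = float(spec.P.mean())
        analytic = 1.0 / (2 * spec.n_sites)
        if not np.isclose(baseline, analytic, rtol=1e-8):
            raise RuntimeError(
                f"baseline {baseline} deviates from analytic 1/(2N) = {analytic}"
            )
    elif mode == "L_only":
        baseline = float(spec.strand("L").mean())
    elif mode == "H_only":
        baseline = float(spec.strand("H").mean())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if baseline <= 0:
        raise ValueError("baseline average must be positive")
    return NormalizedTrack(
        values=spec.P / baseline,
        mode=mode,
        baseline=baseline,
        start=spec.start,
        periodic=spec.periodic,
    )
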