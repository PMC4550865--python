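"""Peak calling on normalized hole tracks and matching to feature positions.

A peak is a strict local maximum of the track on one strand.  On a periodic
segment the first and last positions are interior points (neighbours wrap);
on a linear segment the ends are eligible only under an explicit
``include_ends`` policy.  A plateau (run of equal values strictly above both
flanks) yields a single peak at its leftmost position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .spectrum import NormalizedTrack

__all__ = ["Peak", "MatchReport", "call_peaks", "top_k_peaks", "match_to_features"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    position: int  # 1-based genomic coordinate
    strand: str
    height: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


def _plateau_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of equal consecutive values, in index order."""
    runs = []
    i = 0
    n = len(x)
    while i < n:
        j = i + 1
        while j < n and x[j] == x[i]:
            j += 1
        runs.append((i, j))
        i = j
    return runs


def _local_maxima(x: np.ndarray, periodic: bool, include_ends: bool) -> list[int]:
    """Indices of strict local maxima, plateaus collapsed to their left edge."""
    n = len(x)
    if n == 0:
        raise ValueError("empty track")
    if np.all(x == x[0]):
        return []  # a constant track has no strict maxima
    out = []
    if periodic:
        # rotate so index 0 starts a fresh run, making runs non-wrapping
        shift = 0
        while x[shift] == x[shift - 1]:
            shift += 1
        y = np.roll(x, -shift)
        for i, j in _plateau_runs(y):
            if y[i] > y[i - 1] and y[i] > y[j % n]:
                out.append((i + shift) % n)
    else:
        for i, j in _plateau_runs(x):
            left_ok = (i > 0 and x[i] > x[i - 1]) or (i == 0 and include_ends)
            right_ok = (j < n and x[i] > x[j]) or (j == n and include_ends)
            if i == 0 and j == n:
                continue
            if left_ok and right_ok:
                out.append(i)
    return sorted(out)


def call_peaks(
    track: NormalizedTrack,
    strand: str = "L",
    min_height: float = 0.0,
    include_ends: bool = False,
) -> list[Peak]:
    """Strict local maxima of one strand with height above ``min_height``.

    Returned sorted by descending height, ties broken by smaller coordinate.
    ``include_ends`` applies only to non-periodic tracks, where it makes the
    segment ends eligible as peaks.
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    x = np.asarray(track.strand(strand), dtype=float)
    idx = _local_maxima(x, periodic=track.periodic, include_ends=include_ends)
    peaks = [
        Peak(position=track.start + i, strand=strand, height=float(x[i]))
        for i in idx
        if x[i] > min_height
    ]
    return sorted(peaks, key=lambda p: (-p.height, p.position))


def top_k_peaks(
    track: NormalizedTrack, strand: str = "L", k: int = 1, include_ends: bool = False
) -> list[Peak]:
    """The ``k`` highest peaks (no height threshold); ties go to the smaller
    coordinate.  If fewer than ``k`` peaks exist, all are returned and a
    warning is logged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    peaks = call_peaks(track, strand=strand, min_height=0.0, include_ends=include_ends)
    if len(peaks) < k:
        logger.warning("requested top %d peaks but only %d exist", k, len(peaks))
    return peaks[:k]


@dataclass(frozen=True)
class MatchReport:
    """Peak-to-feature matching at a set of distance tolerances (bp).

    ``counts[d]`` is the number of peaks whose nearest feature lies within
    d bp; counts are non-decreasing in d by construction.
    """

    tolerances: tuple[int, ...]
    counts: dict[int, int]
    fractions: dict[int, float]
    nearest_distance: dict[int, int] = field(repr=False)  # peak position -> bp

    @property
    def n_peaks(self) -> int:
        return len(self.nearest_distance)


def match_to_features(
    peaks: Sequence[Peak],
    feature_positions: Iterable[int],
    tolerances: Sequence[int] = (0, 1, 4),
) -> MatchReport:
    """Distance of each peak to its nearest feature, tallied per tolerance.

    Distances are in genomic coordinates; feature order is irrelevant.
    """
    features = np.unique(np.fromiter(feature_positions, dtype=int))
    if features.size == 0:
        raise ValueError("feature positions must be non-empty")
    tolerances = tuple(sorted(int(t) for t in tolerances))
    nearest: dict[int, int] = {}
    for p in peaks:
        nearest[p.position] = int(np.min(np.abs(features - p.position)))
    counts = {d: sum(1 for v in nearest.values() if v <= d) for d in tolerances}
    n = max(len(peaks), 1)
    fractions = {d: counts[d] / n for d in tolerances}
    return MatchReport(
        tolerances=tolerances, counts=counts, fractions=fractions,
        nearest_distance=nearest,
    )
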