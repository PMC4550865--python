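"""Variant-frequency tracks: capping, smoothing, correlation, constraint.

The per-site variant frequency g (occurrence counts of each variant among
sequenced genomes, alleles summed per site) is compared against hole tracks
in three ways:

* Pearson's r between the (optionally capped and smoothed) tracks.  Capping
  g at a maximum (default 350) mitigates the amplifying effect of
  reproduction and selection on a few high-frequency variants; an
  exponential moving average widens peaks so that maxima offset by a couple
  of base pairs still overlap.
* Variant-constrained scaling N' = N / (A g + 1): hole heights (or disease
  mutation indicators m) are suppressed where g is large, so the peaks
  surviving at large A are those at sites with little or no germline
  variation - candidate critical base pairs and driver mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "VariantTrack",
    "MutationTrack",
    "CorrelationConfig",
    "ConstrainedTrack",
    "cap_frequencies",
    "ema_smooth",
    "pearson_r",
    "variant_constrain",
    "correlation_pipeline",
]


@dataclass(frozen=True)
class VariantTrack:
    """Per-position variant frequency g on a contiguous segment."""

    g: np.ndarray
    start: int = 1

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if np.any(g < 0):
            raise ValueError("variant frequencies must be non-negative")
        object.__setattr__(self, "g", g)

    @property
    def end(self) -> int:
        return self.start + len(self.g) - 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    @classmethod
    def from_counts(cls, counts: Mapping[int, float], start: int, end: int) -> "VariantTrack":
        """Dense track over [start, end]; positions absent from ``counts``
        are zero, positions outside the segment are ignored."""
        g = np.zeros(end - start + 1)
        for pos, c in counts.items():
            if start <= pos <= end:
                g[pos - start] += c
        return cls(g=g, start=start)


@dataclass(frozen=True)
class MutationTrack:
    """Indicator track for disease-implicated mutations.

    ``m`` is a configurable constant (display scale; 1 by default) where a
    mutation is present and zero otherwise; ``labels`` maps positions to
    annotations such as the disease name or an inherited/somatic flag.
    """

    m: np.ndarray
    start: int = 1
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if np.any(m < 0):
            raise ValueError("mutation indicator must be non-negative")
        object.__setattr__(self, "m", m)

    @property
    def end(self) -> int:
        return self.start + len(self.m) - 1

    @property
    def positions_present(self) -> np.ndarray:
        return np.flatnonzero(self.m > 0) + self.start

    @classmethod
    def from_positions(
        cls,
        positions: Mapping[int, str],
        start: int,
        end: int,
        magnitude: float = 1.0,
    ) -> "MutationTrack":
        m = np.zeros(end - start + 1)
        labels = {}
        for pos, label in positions.items():
            if start <= pos <= end:
                m[pos - start] = magnitude
                labels[pos] = label
        return cls(m=m, start=start, labels=labels)


@dataclass(frozen=True)
class CorrelationConfig:
    """Knobs of the hole-variant correlation pipeline."""

    gb_cap: float = 350.0
    ema_halfwidth: int = 8
    ema_decay: float = 0.5
    subrange: tuple[int, int] | None = None  # 1-based inclusive, e.g. (3400, 4000)

    def __post_init__(self) -> None:
        if self.gb_cap <= 0:
            raise ValueError("gb_cap must be positive")
        if self.ema_halfwidth < 0:
            raise ValueError("ema_halfwidth must be >= 0")
        if not (0 < self.ema_decay <= 1):
            raise ValueError("ema_decay must lie in (0, 1]")


def cap_frequencies(v: VariantTrack, cap: float = 350.0) -> VariantTrack:
    """Clip frequencies elementwise at ``cap``; idempotent."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return VariantTrack(g=np.minimum(v.g, cap), start=v.start)


def ema_smooth(values: np.ndarray, halfwidth: int = 8, decay: float = 0.5) -> np.ndarray:
    """Exponential moving average over +/- ``halfwidth`` neighbours.

    Weights are proportional to ``decay ** |j|`` and renormalized to sum to
    one over the in-range neighbours (segment ends truncate and
    renormalize), so a constant track is preserved and the total mass of an
    interior-supported signal is conserved.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if not (0 < decay <= 1):
        raise ValueError("decay must lie in (0, 1]")
    x = np.asarray(values, dtype=float)
    if halfwidth == 0:
        return x.copy()
    n = len(x)
    w = decay ** np.abs(np.arange(-halfwidth, halfwidth + 1))
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - halfwidth)
        hi = min(n, i + halfwidth + 1)
        ww = w[lo - i + halfwidth : hi - i + halfwidth]
        out[i] = np.dot(ww, x[lo:hi]) / ww.sum()
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length tracks.

    Zero variance in either input is an error (the coefficient is
    undefined), not a NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 positions to correlate")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.dot(dx, dx))
    sy = np.sqrt(np.dot(dy, dy))
    if sx == 0 or sy == 0:
        raise ValueError("Pearson r undefined: an input has zero variance")
    r = float(np.dot(dx, dy) / (sx * sy))
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class ConstrainedTrack:
    """Variant-suppressed heights N' = N / (A g + 1)."""

    values: np.ndarray
    A: float
    start: int


def variant_constrain(values: np.ndarray, v: VariantTrack, A: float) -> ConstrainedTrack:
    """Suppress ``values`` where the variant frequency is large.

    Identity at A = 0; at a site with g = 0 the value is never changed; as
    A grows, N' decreases monotonically toward N * [g == 0].
    """
    if A < 0:
        raise ValueError("scale factor A must be >= 0")
    x = np.asarray(values, dtype=float)
    if x.shape != v.g.shape:
        raise ValueError(f"length mismatch: track {x.shape} vs variants {v.g.shape}")
    return ConstrainedTrack(values=x / (A * v.g + 1.0), A=A, start=v.start)


def correlation_pipeline(
    hole_values: np.ndarray,
    v: VariantTrack,
    config: CorrelationConfig | None = None,
) -> dict[str, float]:
    """r-values for the standard configurations.

    Keys: ``raw``, ``capped`` (g clipped at ``gb_cap``), ``smoothed`` (cap
    plus EMA of both tracks); each repeated with suffix ``_sub`` over
    ``config.subrange`` when one is given.  Both tracks are smoothed before
    correlating, which increases their direct overlap when peaks are offset
    by a few base pairs.
    """
    config = config or CorrelationConfig()
    p = np.asarray(hole_values, dtype=float)
    if p.shape != v.g.shape:
        raise ValueError(f"length mismatch: holes {p.shape} vs variants {v.g.shape}")
    if config.subrange is not None:
        lo, hi = config.subrange
        if not (v.start <= lo <= hi <= v.end):
            raise ValueError(f"subrange {lo}-{hi} outside segment {v.start}-{v.end}")
    capped = cap_frequencies(v, config.gb_cap)
    p_s = ema_smooth(p, config.ema_halfwidth, config.ema_decay)
    g_s = ema_smooth(capped.g, config.ema_halfwidth, config.ema_decay)
    variants = {"raw": (p, v.g), "capped": (p, capped.g), "smoothed": (p_s, g_s)}
    out = {name: pearson_r(a, b) for name, (a, b) in variants.items()}
    if config.subrange is not None:
        lo, hi = config.subrange
        i, j = lo - v.start, hi - v.start + 1
        for name, (a, b) in variants.items():
            out[name + "_sub"] = pearson_r(a[i:j], b[i:j])
    return out
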