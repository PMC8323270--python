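"""Delay embedding (phase-space reconstruction) of scalar EEG channels.

A scalar series ``x_0 .. x_{N-1}`` is lifted to the m-dimensional trajectory
whose point t is ``(x_t, x_{t+l}, ..., x_{t+(m-1)l})``, with delay ``l`` in
samples and embedding dimension ``m``.  The trajectory has exactly
``N - (m-1)*l`` points.  Delay selection uses the first minimum of the
lagged auto mutual information; dimension selection uses the false-nearest-
neighbour (FNN) criterion.  Both are standard nonlinear-time-series practice;
the defaults can be overridden in the run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "EmbeddedSeries",
    "SeriesTooShortError",
    "DegenerateSeriesError",
    "embed",
    "choose_delay",
    "choose_dimension",
]


class SeriesTooShortError(ValueError):
    """Series shorter than the minimum length the embedding requires."""


class DegenerateSeriesError(ValueError):
    """Raised for constant (zero-variance) input series."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay ``delay_l`` (samples) and dimension ``dim_m`` of an embedding."""

    delay_l: int
    dim_m: int

    def __post_init__(self) -> None:
        if self.delay_l < 1:
            raise ValueError(f"delay_l must be >= 1, got {self.delay_l}")
        if self.dim_m < 1:
            raise ValueError(f"dim_m must be >= 1, got {self.dim_m}")

    def min_length(self) -> int:
        """Smallest series length that yields at least one embedded point."""
        return (self.dim_m - 1) * self.delay_l + 1


@dataclass(frozen=True)
class EmbeddedSeries:
    """An embedded trajectory: points array of shape (n_points, dim_m)."""

    points: np.ndarray
    params: EmbeddingParams
    source_channel: Optional[object] = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def embed(series: np.ndarray, params: EmbeddingParams,
          source_channel=None) -> EmbeddedSeries:
    """Delay-embed a scalar series.

    Point ``t`` has components ``(x_t, x_{t+l}, ..., x_{t+(m-1)l})`` for
    0-based ``t`` in ``0 .. N-(m-1)l-1``.
    """
    x = np.asarray(series, dtype=float).ravel()
    m, l = params.dim_m, params.delay_l
    n_points = x.size - (m - 1) * l
    if n_points < 1:
        raise SeriesTooShortError(
            f"series of length {x.size} too short for m={m}, l={l}; "
            f"need at least {params.min_length()} samples"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    idx = np.arange(n_points)[:, None] + l * np.arange(m)[None, :]
    return EmbeddedSeries(points=x[idx], params=params,
                          source_channel=source_channel)


def _auto_mi(x: np.ndarray, lag: int, bins: int) -> float:
    """Plug-in mutual information (bits) between x_t and x_{t+lag}."""
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    h_joint = -np.sum(p[nz] * np.log2(p[nz]))
    h_a = -np.sum(pa[pa > 0] * np.log2(pa[pa > 0]))
    h_b = -np.sum(pb[pb > 0] * np.log2(pb[pb > 0]))
    return max(h_a + h_b - h_joint, 0.0)


def choose_delay(series: np.ndarray, max_lag: int = 50) -> int:
    """Delay selection: first minimum of the lagged auto-MI curve.

    The descent of the auto-MI curve often bottoms out in a near-flat
    valley (a pure sine is the extreme case); the returned lag is the
    median of the valley lags, which lands on the quarter period for a
    sine.  White noise, whose auto-MI is already at the estimator floor at
    lag 1, returns 1.  Returns ``max_lag`` if the curve never rises.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    x = np.asarray(series, dtype=float).ravel()
    if x.size < max_lag + 2:
        raise SeriesTooShortError(
            f"series of length {x.size} too short for max_lag={max_lag}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has no informative delay")
    bins = max(4, int(np.ceil((x.size) ** (1 / 3))))
    bins = min(bins, 32)
    mi = np.array([_auto_mi(x, lag, bins) for lag in range(1, max_lag + 1)])
    # already at the estimator floor at lag 1 (white noise): no structure
    floor = (bins - 1) ** 2 / ((x.size - 1) * np.log(2))
    if mi[0] <= floor:
        return 1
    rel = 0.02  # flat-valley tolerance
    running_min = mi[0]
    end = max_lag
    for k in range(1, max_lag):
        if mi[k] > running_min * (1 + rel):
            end = k
            break
        running_min = min(running_min, mi[k])
    if end == max_lag:
        return max_lag
    valley = mi[:end]
    vmin = valley.min()
    plateau = np.nonzero(valley <= vmin * (1 + rel))[0]
    return int(np.median(plateau)) + 1  # lags are 1-based


def _fnn_fraction(x: np.ndarray, l: int, m: int,
                  r_tol: float = 10.0, a_tol: float = 2.0) -> float:
    """Fraction of false nearest neighbours going from dimension m to m+1."""
    n_points = x.size - m * l  # points that exist in both m and m+1 dims
    if n_points < 10:
        raise SeriesTooShortError(
            f"series of length {x.size} too short for FNN at m={m}, l={l}"
        )
    idx = np.arange(n_points)[:, None] + l * np.arange(m)[None, :]
    pts = x[idx]
    tree = cKDTree(pts)
    # nearest neighbour other than self
    dist, nbr = tree.query(pts, k=2)
    d_m = dist[:, 1]
    j = nbr[:, 1]
    extra = np.abs(x[np.arange(n_points) + m * l] - x[j + m * l])
    sigma = x.std()
    # (near-)duplicate points, e.g. from exactly periodic series, are false
    # neighbours iff their continuations diverge
    dup = d_m <= 1e-9 * sigma
    pos = ~dup
    ratio = np.zeros_like(d_m)
    ratio[pos] = extra[pos] / d_m[pos]
    d_m1 = np.sqrt(d_m**2 + extra**2)
    false = np.where(pos,
                     (ratio > r_tol) | (d_m1 > a_tol * sigma),
                     extra > 1e-6 * sigma)
    return float(false.mean())


def choose_dimension(series: np.ndarray, delay_l: int, max_dim: int = 5,
                     tol: float = 0.05) -> int:
    """Dimension selection: smallest m whose FNN fraction drops below tol.

    Returns ``max_dim`` when no tested dimension unfolds the trajectory
    (the i.i.d.-noise case).
    """
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    x = np.asarray(series, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series cannot be embedded")
    for m in range(1, max_dim):
        if _fnn_fraction(x, delay_l, m) < tol:
            return m
    return max_dim
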