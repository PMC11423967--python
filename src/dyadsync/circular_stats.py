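"""Circular descriptive statistics for relative-phase angles (degrees).

Angles live on [-180, 180).  The circular mean is the direction of the
resultant vector of unit phasors; its length R in [0, 1] measures
concentration.  Histograms use bins centred on multiples of the bin width
(so, with the default 20 bins, centres fall on multiples of 18 degrees),
and the distribution peak is the centre of the fullest bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleSample",
    "CircularMean",
    "PhaseHistogram",
    "PeakAngle",
    "wrap_deg",
    "circular_mean",
    "phase_histogram",
    "peak_angle",
]

DEFAULT_N_BINS = 20

_UNDEFINED_R = 1e-12


def wrap_deg(x):
    """Wrap angle(s) in degrees to [-180, 180).

    +180 maps to -180.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=np.float64)
    out = x - 360.0 * np.round(x / 360.0)
    out = np.where(out >= 180.0, out - 360.0, out)
    out = np.where(out < -180.0, out + 360.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass
class AngleSample:
    """A sample of angles with optional non-negative weights."""

    angles: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        if self.weights is not None:
            self.weights = np.atleast_1d(np.asarray(self.weights, dtype=np.float64))
            if self.weights.shape != self.angles.shape:
                raise ValueError(
                    f"weights shape {self.weights.shape} != angles shape "
                    f"{self.angles.shape}"
                )
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            if not np.any(self.weights > 0):
                raise ValueError("weights must not be all zero")


@dataclass(frozen=True)
class CircularMean:
    """Circular mean direction and resultant length.

    ``defined`` is False (and ``mean_deg`` is NaN) when the resultant is
    numerically zero, e.g. for perfectly uniform angles.
    """

    mean_deg: float
    resultant_length: float
    defined: bool = True


def circular_mean(s: AngleSample | np.ndarray) -> CircularMean:
    """Weighted circular mean: atan2 of the summed unit phasors."""
    if not isinstance(s, AngleSample):
        s = AngleSample(np.asarray(s))
    if s.angles.size == 0:
        raise ValueError("circular_mean of an empty sample")
    w = np.ones_like(s.angles) if s.weights is None else s.weights
    t = np.deg2rad(s.angles)
    z = np.sum(w * np.exp(1j * t)) / np.sum(w)
    r = float(np.abs(z))
    if r < _UNDEFINED_R:
        return CircularMean(float("nan"), r, defined=False)
    return CircularMean(wrap_deg(np.rad2deg(np.angle(z))), r)


@dataclass(frozen=True)
class PhaseHistogram:
    """Circular histogram: probabilities per bin summing to 1."""

    bin_centers_deg: np.ndarray
    probabilities: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_centers_deg.size

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.n_bins


def phase_histogram(
    s: AngleSample | np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> PhaseHistogram:
    """Circular histogram with bin centres at ``k * 360 / n_bins - 180``.

    The first bin is centred on -180 and wraps around the circle; each bin
    covers ``[centre - w/2, centre + w/2)`` with ``w = 360 / n_bins``.
    Weighted samples contribute their weights.
    """
    if not isinstance(s, AngleSample):
        s = AngleSample(np.asarray(s))
    if s.angles.size == 0:
        raise ValueError("phase_histogram of an empty sample")
    if n_bins < 4 or 360 % n_bins != 0:
        raise ValueError(f"n_bins must be >= 4 and divide 360, got {n_bins}")
    w = 360.0 / n_bins
    angles = wrap_deg(np.asarray(s.angles))
    # shift by half a bin so centres sit at k*w - 180
    idx = np.floor((angles + 180.0 + w / 2.0) / w).astype(int) % n_bins
    weights = np.ones_like(angles) if s.weights is None else s.weights
    counts = np.bincount(idx, weights=weights, minlength=n_bins)
    centers = wrap_deg(np.arange(n_bins) * w - 180.0)
    return PhaseHistogram(centers, counts / counts.sum())


@dataclass(frozen=True)
class PeakAngle:
    """Centre of the fullest histogram bin; ties flagged and broken
    toward 0 degrees, then toward the smaller angle."""

    angle_deg: float
    probability: float
    tied: bool = False


def peak_angle(hist: PhaseHistogram) -> PeakAngle:
    """Peak of the circular distribution (centre of the maximal bin)."""
    p = hist.probabilities
    top = np.flatnonzero(p >= p.max() - 1e-15)
    centers = hist.bin_centers_deg[top]
    order = sorted(range(top.size), key=lambda i: (abs(centers[i]), centers[i]))
    best = order[0]
    return PeakAngle(
        angle_deg=float(centers[best]),
        probability=float(p[top[best]]),
        tied=top.size > 1,
    )
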