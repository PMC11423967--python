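"""Morlet continuous wavelet transform, cross-wavelet coherence and
relative phase, and aggregation over timescale bands.

The transform follows the standard FFT formulation of the Morlet CWT with
centre frequency ``omega0`` (default 6, for which the Fourier period is
about 1.033 x scale).  Coherence is the magnitude-squared of the smoothed
cross-spectrum normalised by the smoothed auto-spectra; smoothing is a
scale-matched Gaussian in time followed by a boxcar across scales.
Without smoothing, wavelet coherence is identically 1, so smoothing
parameters are part of the coherence definition and are exposed.

Sign convention for relative phase: positive means the first-named series
leads (is earlier in time) at that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft

from .circular_stats import AngleSample, circular_mean, wrap_deg
from .series import UniformSeries

__all__ = [
    "ScaleGrid",
    "WaveletParams",
    "WaveletSpectrum",
    "CoherenceMap",
    "PhaseMap",
    "TimescaleBands",
    "BandStats",
    "BandSummary",
    "make_scale_grid",
    "default_grid",
    "cwt_morlet",
    "cross_wavelet",
    "smoothed_cross_spectra",
    "wavelet_coherence",
    "relative_phase",
    "coherence_and_phase",
    "band_average",
    "default_bands",
    "pair_band_summary",
]

DEFAULT_OMEGA0 = 6.0
DEFAULT_VOICES_PER_OCTAVE = 16
DEFAULT_MIN_PERIOD_S = 0.125
DEFAULT_MAX_PERIOD_S = 32.0
DEFAULT_SMOOTHING_OCTAVES = 0.6

#: the default 23 timescale ranges in seconds, half-open (lo, hi]
DEFAULT_BAND_EDGES_S = (
    0.125, 0.25, 0.375, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
    12, 14, 16, 18, 20, 22, 24, 26, 28, 30,
)


def fourier_factor(omega0: float = DEFAULT_OMEGA0) -> float:
    """Ratio of Fourier period to Morlet scale: 4*pi / (w0 + sqrt(2 + w0^2))."""
    return 4.0 * math.pi / (omega0 + math.sqrt(2.0 + omega0 ** 2))


@dataclass(frozen=True)
class ScaleGrid:
    """Geometric grid of timescales (wavelet Fourier periods, seconds)."""

    periods: np.ndarray
    voices_per_octave: int

    def __post_init__(self) -> None:
        p = np.asarray(self.periods, dtype=np.float64)
        object.__setattr__(self, "periods", p)
        if p.size < 2 or np.any(np.diff(p) <= 0):
            raise ValueError("periods must be a strictly increasing grid")
        ratios = p[1:] / p[:-1]
        if np.max(np.abs(ratios / ratios[0] - 1.0)) > 1e-9:
            raise ValueError("periods must be geometrically spaced")

    @property
    def n_scales(self) -> int:
        return self.periods.size


def make_scale_grid(
    min_period: float = DEFAULT_MIN_PERIOD_S,
    max_period: float = DEFAULT_MAX_PERIOD_S,
    voices_per_octave: int = DEFAULT_VOICES_PER_OCTAVE,
) -> ScaleGrid:
    """Geometric period grid from ``min_period`` up to ``max_period``."""
    if not 0 < min_period < max_period:
        raise ValueError(
            f"need 0 < min_period < max_period, got {min_period}, {max_period}"
        )
    n = int(math.floor(voices_per_octave * math.log2(max_period / min_period))) + 1
    periods = min_period * 2.0 ** (np.arange(n) / voices_per_octave)
    return ScaleGrid(periods, voices_per_octave)


def default_grid() -> ScaleGrid:
    return make_scale_grid()


@dataclass(frozen=True)
class WaveletParams:
    """All knobs of the wavelet/coherence computation."""

    omega0: float = DEFAULT_OMEGA0
    voices_per_octave: int = DEFAULT_VOICES_PER_OCTAVE
    min_period: float = DEFAULT_MIN_PERIOD_S
    max_period: float = DEFAULT_MAX_PERIOD_S
    smoothing_octaves: float = DEFAULT_SMOOTHING_OCTAVES
    exclude_coi: bool = True

    def grid(self) -> ScaleGrid:
        return make_scale_grid(
            self.min_period, self.max_period, self.voices_per_octave
        )


@dataclass
class WaveletSpectrum:
    """Complex Morlet CWT coefficients on a (scale, time) grid.

    ``coi`` holds, per time sample, the maximum trustworthy period in
    seconds (the e-folding criterion); bins with period above it are
    edge-affected.
    """

    coeffs: np.ndarray  # (n_scales, n_times) complex
    grid: ScaleGrid
    rate: float
    coi: np.ndarray  # (n_times,) seconds
    omega0: float = DEFAULT_OMEGA0

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[1]

    @property
    def scales(self) -> np.ndarray:
        return self.grid.periods / fourier_factor(self.omega0)

    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    def coi_mask(self) -> np.ndarray:
        """(n_scales, n_times) boolean: True where inside the COI region
        (i.e. edge-affected, to be excluded)."""
        return self.grid.periods[:, None] > self.coi[None, :]


@dataclass
class CoherenceMap:
    """Wavelet coherence in [0, 1] per (scale, time) bin."""

    values: np.ndarray
    grid: ScaleGrid
    rate: float
    coi: np.ndarray
    degenerate: bool = False  # all-zero input: coherence undefined

    def coi_mask(self) -> np.ndarray:
        return self.grid.periods[:, None] > self.coi[None, :]


@dataclass
class PhaseMap:
    """Relative phase in degrees, in [-180, 180), per (scale, time) bin.

    Positive values mean the first-named series leads.  Bins with no
    cross-power are NaN (missing).
    """

    values: np.ndarray
    grid: ScaleGrid
    rate: float
    coi: np.ndarray

    def coi_mask(self) -> np.ndarray:
        return self.grid.periods[:, None] > self.coi[None, :]


def cwt_morlet(
    s: UniformSeries,
    grid: ScaleGrid | None = None,
    omega0: float = DEFAULT_OMEGA0,
) -> WaveletSpectrum:
    """Morlet CWT of a series on a period grid.

    The series mean is removed and the series zero-padded to the next
    power of two.  The COI is the e-folding time of the Morlet envelope,
    ``sqrt(2) * scale`` from each edge.
    """
    if omega0 < 5:
        raise ValueError(f"omega0 must be >= 5 for admissibility, got {omega0}")
    if grid is None:
        grid = default_grid()
    n = len(s)
    dt = 1.0 / s.rate
    ff = fourier_factor(omega0)
    max_period = float(grid.periods[-1])
    if n * dt < 2.0 * max_period:
        raise ValueError(
            f"series of {n * dt:g}s is too short for max period "
            f"{max_period:g}s (need >= {2 * max_period:g}s)"
        )
    n_fft = 1 << max(1, (n - 1).bit_length())
    x = s.values - s.values.mean()
    xh = fft(x, n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=dt)  # rad/s
    scales = grid.periods / ff  # (n_scales,)
    # Morlet daughter in frequency domain, positive frequencies only
    arg = scales[:, None] * omega[None, :] - omega0
    psi_hat = (np.pi ** -0.25) * np.exp(-0.5 * arg ** 2) * (omega[None, :] > 0)
    norm = np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    W = ifft(xh[None, :] * (psi_hat * norm), axis=1)[:, :n]
    t = np.arange(n) * dt
    edge = np.minimum(t, (n - 1) * dt - t)
    coi = ff * edge / math.sqrt(2.0)
    return WaveletSpectrum(W, grid, s.rate, coi, omega0)


def _check_compatible(a: WaveletSpectrum, b: WaveletSpectrum) -> None:
    if a.grid.n_scales != b.grid.n_scales or not np.allclose(
        a.grid.periods, b.grid.periods
    ):
        raise ValueError("wavelet spectra have different scale grids")
    if a.rate != b.rate:
        raise ValueError(f"rate mismatch: {a.rate} vs {b.rate}")
    if a.n_times != b.n_times:
        raise ValueError(f"length mismatch: {a.n_times} vs {b.n_times}")


def cross_wavelet(a: WaveletSpectrum, b: WaveletSpectrum) -> WaveletSpectrum:
    """Cross-wavelet spectrum ``Wa * conj(Wb)``; COI = elementwise min."""
    _check_compatible(a, b)
    return WaveletSpectrum(
        a.coeffs * np.conj(b.coeffs),
        a.grid,
        a.rate,
        np.minimum(a.coi, b.coi),
        a.omega0,
    )


def _smooth_time(
    fields: np.ndarray, scales: np.ndarray, rate: float
) -> np.ndarray:
    """Gaussian smoothing along the last axis, std matched to each scale.

    ``fields`` is (..., n_scales, n_times); the kernel for scale s is
    exp(-t^2 / (2 s^2)), applied in the frequency domain
    (kernel exp(-0.5 (s w)^2)).  The implied circular wrap only affects
    edge bins, which sit inside the COI.
    """
    from scipy.fft import next_fast_len

    n = fields.shape[-1]
    n_fft = next_fast_len(int(1.25 * n))
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=1.0 / rate)
    kernel = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)
    sm = ifft(fft(fields, n_fft, axis=-1) * kernel, axis=-1)[..., :n]
    return sm


def _smooth_scale(fields: np.ndarray, grid: ScaleGrid, octaves: float) -> np.ndarray:
    """Boxcar across scales (axis -2) spanning ``octaves`` octaves of period."""
    if octaves <= 0:
        return fields
    half = max(0, int(round(octaves * grid.voices_per_octave / 2.0)))
    if half == 0:
        return fields
    n_s = fields.shape[-2]
    out = np.empty_like(fields)
    csum = np.cumsum(fields, axis=-2)
    for i in range(n_s):
        lo = max(0, i - half)
        hi = min(n_s - 1, i + half)
        total = csum[..., hi, :] - (csum[..., lo - 1, :] if lo > 0 else 0)
        out[..., i, :] = total / (hi - lo + 1)
    return out


def smoothed_cross_spectra(
    a: WaveletSpectrum,
    b: WaveletSpectrum,
    params: WaveletParams | None = None,
):
    """Smoothed (cross, auto-a, auto-b) spectra used by coherence and phase.

    Each field is divided by scale before smoothing (the usual bias
    correction for the Morlet CWT's scale-dependent energy density).
    """
    if params is None:
        params = WaveletParams()
    _check_compatible(a, b)
    scales = a.scales
    inv_s = 1.0 / scales[:, None]

    stacked = np.stack(
        [
            a.coeffs * np.conj(b.coeffs),
            (a.coeffs.real ** 2 + a.coeffs.imag ** 2).astype(complex),
            (b.coeffs.real ** 2 + b.coeffs.imag ** 2).astype(complex),
        ]
    )
    sm = _smooth_time(stacked * inv_s[None], scales, a.rate)
    sm = _smooth_scale(sm, a.grid, params.smoothing_octaves)
    s_ab, s_aa, s_bb = sm[0], sm[1].real, sm[2].real
    coi = np.minimum(a.coi, b.coi)
    return s_ab, s_aa, s_bb, coi


def coherence_and_phase(
    a: WaveletSpectrum,
    b: WaveletSpectrum,
    params: WaveletParams | None = None,
) -> tuple[CoherenceMap, PhaseMap]:
    """Wavelet coherence and relative phase from one shared smoothing pass."""
    s_ab, s_aa, s_bb, coi = smoothed_cross_spectra(a, b, params)
    denom = s_aa * s_bb
    degenerate = bool(np.all(np.abs(a.coeffs) == 0) or np.all(np.abs(b.coeffs) == 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(s_ab) ** 2 / denom
    coh = np.where(denom > 0, coh, np.nan)
    coh = np.clip(coh, 0.0, 1.0)
    cross_abs = np.abs(s_ab)
    with np.errstate(invalid="ignore"):
        phase = np.degrees(np.arctan2(s_ab.imag, s_ab.real))
    phase = np.where(cross_abs > 0, wrap_deg(phase), np.nan)
    cmap = CoherenceMap(coh, a.grid, a.rate, coi, degenerate=degenerate)
    pmap = PhaseMap(phase, a.grid, a.rate, coi)
    return cmap, pmap


def wavelet_coherence(
    a: WaveletSpectrum,
    b: WaveletSpectrum,
    params: WaveletParams | None = None,
) -> CoherenceMap:
    """Magnitude-squared coherence of the smoothed cross-spectrum, in [0, 1]."""
    return coherence_and_phase(a, b, params)[0]


def relative_phase(
    a: WaveletSpectrum,
    b: WaveletSpectrum,
    params: WaveletParams | None = None,
) -> PhaseMap:
    """Relative phase (degrees) of the smoothed cross-spectrum.

    Positive phase means ``a`` leads ``b``.
    """
    return coherence_and_phase(a, b, params)[1]


# ---------------------------------------------------------------------------
# timescale bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimescaleBands:
    """Ordered half-open period intervals (lo, hi] in seconds."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}] requires lo < hi")
        for (_lo, prev_hi), (lo, _hi) in zip(self.intervals, self.intervals[1:]):
            if lo < prev_hi:
                raise ValueError("bands must be non-overlapping and ordered")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def default_bands() -> TimescaleBands:
    """The 23 default timescale ranges, (0.125, 0.25] ... (28, 30] s."""
    e = DEFAULT_BAND_EDGES_S
    return TimescaleBands(tuple(zip(e[:-1], e[1:])))


@dataclass(frozen=True)
class BandStats:
    """Per-band summary for one signal pair.

    A band with no valid (finite, out-of-COI) bins is *missing*:
    ``n_valid_bins == 0`` and NaN statistics, never zeros.
    """

    lo: float
    hi: float
    mean_coherence: float
    circ_mean_phase_deg: float
    resultant_length: float
    n_valid_bins: int

    @property
    def missing(self) -> bool:
        return self.n_valid_bins == 0


@dataclass
class BandSummary:
    """Band statistics for one pair, with pair metadata."""

    pair: str
    level: str  # "intra" | "inter"
    modality_class: str  # "unimodal" | "multimodal"
    bands: list[BandStats] = field(default_factory=list)

    def band(self, lo: float, hi: float) -> BandStats:
        for b in self.bands:
            if b.lo == lo and b.hi == hi:
                return b
        raise KeyError(f"no band ({lo}, {hi}]")


def band_average(
    coh: CoherenceMap,
    ph: PhaseMap,
    bands: TimescaleBands | None = None,
    *,
    pair: str = "",
    level: str = "",
    modality_class: str = "",
    exclude_coi: bool = True,
) -> BandSummary:
    """Per-band mean coherence and circular-mean phase over valid bins.

    Valid bins have a period inside the half-open band, lie outside the
    COI (unless ``exclude_coi`` is False) and are finite in both maps.
    """
    if bands is None:
        bands = default_bands()
    periods = coh.grid.periods
    valid = np.isfinite(coh.values) & np.isfinite(ph.values)
    if exclude_coi:
        valid &= ~coh.coi_mask()
    out: list[BandStats] = []
    for lo, hi in bands:
        in_band = (periods > lo) & (periods <= hi)
        mask = valid & in_band[:, None]
        n = int(mask.sum())
        if n == 0:
            out.append(
                BandStats(lo, hi, float("nan"), float("nan"), float("nan"), 0)
            )
            continue
        mean_coh = float(coh.values[mask].mean())
        cm = circular_mean(AngleSample(ph.values[mask]))
        out.append(
            BandStats(
                lo,
                hi,
                mean_coh,
                cm.mean_deg,
                cm.resultant_length,
                n,
            )
        )
    return BandSummary(pair=pair, level=level, modality_class=modality_class, bands=out)


def pair_band_summary(
    sa: UniformSeries | WaveletSpectrum,
    sb: UniformSeries | WaveletSpectrum,
    params: WaveletParams | None = None,
    bands: TimescaleBands | None = None,
    **meta,
) -> BandSummary:
    """Convenience: series (or precomputed spectra) → band summary."""
    if params is None:
        params = WaveletParams()
    grid = params.grid()
    wa = sa if isinstance(sa, WaveletSpectrum) else cwt_morlet(sa, grid, params.omega0)
    wb = sb if isinstance(sb, WaveletSpectrum) else cwt_morlet(sb, grid, params.omega0)
    coh, ph = coherence_and_phase(wa, wb, params)
    return band_average(
        coh, ph, bands, exclude_coi=params.exclude_coi, **meta
    )
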