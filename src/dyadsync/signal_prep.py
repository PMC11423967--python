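"""From raw positions and audio to the three analysis series per participant.

Head speed, summed wrist speed and the voice amplitude envelope are produced
on a common clock (90 Hz by default).  Position data is low-pass filtered
with a zero-phase Butterworth filter before differentiation; the envelope is
the magnitude of the Hilbert analytic signal, smoothed and resampled.

Zero-phase (forward-backward) filtering is used throughout because the
pipeline's downstream quantity of interest is relative phase: a causal
filter would inject a scale-dependent lag into every series.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .errors import SessionError, ValidationError
from .io_formats import MarkerTrajectory
from .series import DyadRecording, ParticipantSeries, UniformSeries

__all__ = [
    "butterworth_lowpass",
    "lowpass_trajectory",
    "speed",
    "sum_wrist_speeds",
    "amplitude_envelope",
    "resample",
    "ParticipantInputs",
    "build_dyad_recording",
]

#: pipeline defaults (all overridable per call / via config)
DEFAULT_FILTER_CUTOFF_HZ = 10.0
DEFAULT_FILTER_ORDER = 2
DEFAULT_ENVELOPE_CUTOFF_HZ = 12.0
DEFAULT_COMMON_RATE_HZ = 90.0


def _butter_sos(cutoff: float, order: int, rate: float):
    if not 0 < cutoff < rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={rate / 2:g}) Hz, got {cutoff:g}"
        )
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    return sps.butter(order, cutoff, btype="low", fs=rate, output="sos")


def butterworth_lowpass(s: UniformSeries, cutoff: float, order: int = 2) -> UniformSeries:
    """Zero-phase Butterworth low-pass of a series.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth magnitude and
    the phase response is identically zero.  Length and rate are preserved.
    """
    sos = _butter_sos(cutoff, order, s.rate)
    out = sps.sosfiltfilt(sos, s.values)
    return UniformSeries(out, s.rate, s.start, s.label)


def lowpass_trajectory(
    traj: MarkerTrajectory, cutoff: float, order: int = 2
) -> MarkerTrajectory:
    """Zero-phase Butterworth low-pass applied to each coordinate."""
    sos = _butter_sos(cutoff, order, traj.rate)
    out = sps.sosfiltfilt(sos, traj.positions, axis=0)
    return MarkerTrajectory(traj.joint, out, traj.rate)


def speed(traj: MarkerTrajectory, label: str = "head_speed") -> UniformSeries:
    """Scalar speed: norm of the central-difference derivative of position.

    Endpoints use one-sided differences (``np.gradient`` convention).
    """
    if traj.positions.shape[0] < 3:
        raise ValueError(
            f"need at least 3 frames to differentiate, got {traj.positions.shape[0]}"
        )
    deriv = np.gradient(traj.positions, 1.0 / traj.rate, axis=0)
    return UniformSeries(np.linalg.norm(deriv, axis=1), traj.rate, 0.0, label)


def sum_wrist_speeds(left: UniformSeries, right: UniformSeries) -> UniformSeries:
    """Element-wise sum of the two wrist speed series."""
    if left.rate != right.rate:
        raise ValueError(f"rate mismatch: {left.rate} vs {right.rate}")
    if len(left) != len(right):
        raise ValueError(f"length mismatch: {len(left)} vs {len(right)}")
    return UniformSeries(
        left.values + right.values, left.rate, left.start, "wrist_speed"
    )


def resample(s: UniformSeries, target_rate: float) -> UniformSeries:
    """Polyphase band-limited resampling to ``target_rate``.

    Duration is preserved to within one sample period of the coarser rate.
    """
    if not target_rate > 0:
        raise ValueError(f"target_rate must be > 0, got {target_rate}")
    if target_rate == s.rate:
        return UniformSeries(s.values.copy(), s.rate, s.start, s.label)
    ratio = Fraction(target_rate / s.rate).limit_denominator(100_000)
    out = sps.resample_poly(s.values, ratio.numerator, ratio.denominator)
    return UniformSeries(out, target_rate, s.start, s.label)


def amplitude_envelope(
    audio: UniformSeries,
    smooth_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    target_rate: float = DEFAULT_COMMON_RATE_HZ,
) -> UniformSeries:
    """Speech amplitude envelope via the Hilbert analytic signal.

    |analytic signal|, low-passed at ``smooth_cutoff`` with a zero-phase
    second-order Butterworth filter, resampled to ``target_rate`` and
    clipped at zero (resampling and filtering can ring slightly negative).
    """
    if not audio.rate > 2 * smooth_cutoff:
        raise ValueError(
            f"audio rate {audio.rate:g} must exceed 2 x smooth_cutoff "
            f"({2 * smooth_cutoff:g})"
        )
    if target_rate > audio.rate:
        raise ValueError(
            f"target_rate {target_rate:g} must not exceed audio rate {audio.rate:g}"
        )
    n = len(audio)
    analytic = hilbert(audio.values, N=next_fast_len(n))[:n]
    env = np.abs(analytic)
    env = butterworth_lowpass(
        UniformSeries(env, audio.rate, audio.start, ""), smooth_cutoff, 2
    )
    out = resample(env, target_rate)
    return UniformSeries(
        np.clip(out.values, 0.0, None), target_rate, audio.start, "voice_env"
    )


@dataclass
class ParticipantInputs:
    """Raw per-participant inputs for one session."""

    head: MarkerTrajectory
    wrist_left: MarkerTrajectory
    wrist_right: MarkerTrajectory
    audio: UniformSeries


def load_participant(
    bvh_path,
    audio_path,
    *,
    head: str = "Head",
    wrist_left: str = "LeftHand",
    wrist_right: str = "RightHand",
    channel: int = 0,
) -> ParticipantInputs:
    """Read one participant's BVH and WAV into :class:`ParticipantInputs`.

    Joint names are matched case-insensitively as substrings (dataset
    naming varies); a missing joint raises a lookup error listing the
    available joints.
    """
    from .io_formats import find_joint, read_audio, read_bvh, world_positions

    anim = read_bvh(bvh_path)
    return ParticipantInputs(
        head=world_positions(anim, find_joint(anim, head)),
        wrist_left=world_positions(anim, find_joint(anim, wrist_left)),
        wrist_right=world_positions(anim, find_joint(anim, wrist_right)),
        audio=read_audio(audio_path, channel=channel),
    )


def _movement_series(
    inputs: ParticipantInputs,
    cutoff: float,
    order: int,
    common_rate: float,
) -> tuple[UniformSeries, UniformSeries]:
    head = speed(lowpass_trajectory(inputs.head, cutoff, order), "head_speed")
    wl = speed(lowpass_trajectory(inputs.wrist_left, cutoff, order), "wrist_speed")
    wr = speed(lowpass_trajectory(inputs.wrist_right, cutoff, order), "wrist_speed")
    wrist = sum_wrist_speeds(wl, wr)
    head = resample(head, common_rate)
    wrist = resample(wrist, common_rate)
    # polyphase edges may ring slightly negative on a non-negative signal
    head = head.with_values(np.clip(head.values, 0.0, None))
    wrist = wrist.with_values(np.clip(wrist.values, 0.0, None))
    return head, wrist


def build_dyad_recording(
    session_id: str,
    a: ParticipantInputs,
    b: ParticipantInputs,
    *,
    common_rate: float = DEFAULT_COMMON_RATE_HZ,
    filter_cutoff: float = DEFAULT_FILTER_CUTOFF_HZ,
    filter_order: int = DEFAULT_FILTER_ORDER,
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
) -> DyadRecording:
    """Assemble the six aligned series of one session.

    Applies filter → speed → wrist sum and envelope → resample per
    participant, then trims all six series to the common overlapping
    window starting at t = 0.
    """
    parts = []
    for pid, inputs in (("A", a), ("B", b)):
        try:
            head, wrist = _movement_series(
                inputs, filter_cutoff, filter_order, common_rate
            )
            env = amplitude_envelope(inputs.audio, envelope_cutoff, common_rate)
        except ValueError as e:
            raise SessionError(
                f"session {session_id!r}, participant {pid}: {e}"
            ) from e
        parts.append((head, wrist, env))

    n = min(len(s) for triple in parts for s in triple)
    if n < 3:
        raise SessionError(
            f"session {session_id!r}: common overlap of {n} samples is too short"
        )

    def trim(s: UniformSeries) -> UniformSeries:
        return UniformSeries(s.values[:n], common_rate, 0.0, s.label)

    (ha, wa, va), (hb, wb, vb) = parts
    try:
        return DyadRecording(
            session_id=session_id,
            a=ParticipantSeries(trim(ha), trim(wa), trim(va)),
            b=ParticipantSeries(trim(hb), trim(wb), trim(vb)),
            rate=common_rate,
        )
    except ValidationError as e:  # pragma: no cover - defensive
        raise SessionError(f"session {session_id!r}: {e}") from e
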