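"""Core time-series containers shared across the pipeline.

A :class:`UniformSeries` is the common currency: a uniformly sampled scalar
signal with a rate and a modality label.  A :class:`DyadRecording` bundles
the six analysis series of one session (head speed, summed wrist speed and
voice envelope for each of two participants) on a common clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: labels whose values must be non-negative by construction
_NONNEGATIVE_LABELS = frozenset({"head_speed", "wrist_speed", "voice_env"})

#: recognised modality labels
SERIES_LABELS = ("head_speed", "wrist_speed", "voice_env", "raw_audio")


@dataclass
class UniformSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values
        Sample values; coerced to a float64 1-D array.
    rate
        Sampling rate in Hz (> 0).
    start
        Time of the first sample in seconds.
    label
        Modality name, one of ``head_speed | wrist_speed | voice_env |
        raw_audio`` (or empty/free-form for intermediate signals).
    """

    values: np.ndarray
    rate: float
    start: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError(
                f"series values must be 1-D, got shape {self.values.shape}"
            )
        if not self.rate > 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("series contains non-finite values")
        if self.label in _NONNEGATIVE_LABELS and self.values.size and (
            self.values.min() < 0
        ):
            raise ValidationError(
                f"{self.label} series must be non-negative "
                f"(min = {self.values.min():g})"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples / rate)."""
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start + np.arange(self.values.size) / self.rate

    def with_values(self, values: np.ndarray, label: str | None = None) -> "UniformSeries":
        """Return a copy with new values (and optionally a new label)."""
        return UniformSeries(
            values, self.rate, self.start, self.label if label is None else label
        )


@dataclass
class ParticipantSeries:
    """The three analysis series of one participant."""

    head_speed: UniformSeries
    wrist_speed: UniformSeries
    voice_env: UniformSeries

    def get(self, modality: str) -> UniformSeries:
        """Return the series for ``modality`` in {head, wrist, voice}."""
        try:
            return {
                "head": self.head_speed,
                "wrist": self.wrist_speed,
                "voice": self.voice_env,
            }[modality]
        except KeyError:
            raise KeyError(
                f"unknown modality {modality!r}; expected head, wrist or voice"
            ) from None


@dataclass
class DyadRecording:
    """Six aligned series (3 per participant) for one dyadic session."""

    session_id: str
    a: ParticipantSeries
    b: ParticipantSeries
    rate: float = field(default=90.0)

    def __post_init__(self) -> None:
        series = list(self.iter_series())
        lengths = {len(s) for _, _, s in series}
        rates = {s.rate for _, _, s in series}
        if len(lengths) != 1:
            raise ValidationError(
                f"all six series must share length, got lengths {sorted(lengths)}"
            )
        if rates != {self.rate}:
            raise ValidationError(
                f"all six series must share rate {self.rate}, got {sorted(rates)}"
            )
        expected = {
            "head_speed": ("head_speed",),
            "wrist_speed": ("wrist_speed",),
            "voice_env": ("voice_env",),
        }
        for participant, name, s in series:
            if s.label not in expected[name]:
                raise ValidationError(
                    f"participant {participant} series {name} has label "
                    f"{s.label!r}"
                )

    def iter_series(self):
        """Yield ``(participant, name, series)`` for all six series."""
        for pid, part in (("A", self.a), ("B", self.b)):
            yield pid, "head_speed", part.head_speed
            yield pid, "wrist_speed", part.wrist_speed
            yield pid, "voice_env", part.voice_env

    def participant(self, pid: str) -> ParticipantSeries:
        if pid == "A":
            return self.a
        if pid == "B":
            return self.b
        raise KeyError(f"unknown participant {pid!r}; expected 'A' or 'B'")

    @property
    def n_samples(self) -> int:
        return len(self.a.head_speed)

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate
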