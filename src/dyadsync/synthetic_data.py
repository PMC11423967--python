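"""Synthetic dyadic sessions with known ground truth.

Generates (a) an alternating turn sequence with configurable overlap
probability at switches, internal pauses, occasional contained
backchannels, and annotation tiers split into sub-interval chunks so the
unit-merging rule is exercised; (b) syllable-scale voice amplitude
envelopes driven by the tiers; and (c) head/wrist speed series built from
1/f background noise with band-limited, phase-locked coupling to a
configured driver signal, so coherence and relative phase at a given
timescale band are known by construction.

The generator keeps its own bookkeeping of the conversational structure
it creates (units, turns, overlaps, switches, silences), which serves as
an independent oracle for the segmentation module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from .errors import ValidationError
from .io_formats import SpeechInterval
from .series import DyadRecording, ParticipantSeries, UniformSeries
from .turn_taking import (
    ConversationStructure,
    Overlap,
    SilenceEvent,
    SpeechUnit,
    Turn,
    TurnEvent,
    DEFAULT_MIN_SILENCE_S,
)

__all__ = [
    "TurnModel",
    "EnvelopeModel",
    "CouplingSpec",
    "DyadSimConfig",
    "SyntheticSession",
    "generate_turn_sequence",
    "generate_envelopes",
    "generate_coupled_movements",
    "generate_session",
    "pink_noise",
    "syllable_pulse_train",
]

#: signal identifiers usable as coupling drivers/targets
SIGNAL_IDS = ("A.head", "A.wrist", "B.head", "B.wrist", "A.voice", "B.voice")
_MOVEMENT_IDS = ("A.head", "A.wrist", "B.head", "B.wrist")


@dataclass(frozen=True)
class TurnModel:
    """Turn-taking generative parameters.

    Defaults are tuned so roughly 70 % of turns last up to 10 s and the
    configured share of switches happens in overlap.
    """

    turn_median_s: float = 6.5
    turn_sigma: float = 0.75
    turn_min_s: float = 1.5
    turn_max_s: float = 40.0
    unit_median_s: float = 2.0
    unit_sigma: float = 0.5
    unit_min_s: float = 0.6
    unit_max_s: float = 6.0
    pause_range_s: tuple[float, float] = (0.25, 0.7)
    overlap_prob: float = 0.7
    overlap_range_s: tuple[float, float] = (0.2, 0.8)
    gap_range_s: tuple[float, float] = (0.25, 1.0)
    backchannel_prob: float = 0.05
    backchannel_range_s: tuple[float, float] = (0.2, 0.5)
    #: probability that a unit is split into raw tier chunks separated by
    #: silences shorter than the merge threshold
    micro_split_prob: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.overlap_prob, self.backchannel_prob, self.micro_split_prob):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.overlap_range_s[1] >= self.turn_min_s:
            raise ValidationError(
                "overlaps must be shorter than the shortest turn "
                f"({self.overlap_range_s[1]} >= {self.turn_min_s})"
            )


@dataclass(frozen=True)
class EnvelopeModel:
    """Voice-envelope generative parameters (syllable-scale bumps)."""

    syllable_rate_hz: float = 4.0
    syllable_s: float = 0.2
    amp_jitter: float = 0.3
    onset_jitter_s: float = 0.03
    noise_floor: float = 0.01


@dataclass(frozen=True)
class CouplingSpec:
    """Phase-locked band-limited coupling of one signal to a driver.

    ``lag_deg`` is the relative phase by which the *driver* leads the
    target; a pair analysed as (driver, target) recovers ``+lag_deg``,
    and as (target, driver) recovers ``-lag_deg``.
    """

    target: str
    driver: str
    band_s: tuple[float, float]
    strength: float
    lag_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in _MOVEMENT_IDS:
            raise ValidationError(
                f"coupling target must be a movement signal, got {self.target!r}"
            )
        if self.driver not in SIGNAL_IDS:
            raise ValidationError(f"unknown driver {self.driver!r}")
        if self.driver == self.target:
            raise ValidationError("driver and target must differ")
        if not 0 <= self.strength <= 1:
            raise ValidationError(f"strength must be in [0, 1], got {self.strength}")
        lo, hi = self.band_s
        if not 0 < lo < hi:
            raise ValidationError(f"invalid band ({lo}, {hi}]")


@dataclass(frozen=True)
class DyadSimConfig:
    """Full configuration of one synthetic session."""

    duration_s: float = 300.0
    rate: float = 90.0
    turns: TurnModel = field(default_factory=TurnModel)
    envelope: EnvelopeModel = field(default_factory=EnvelopeModel)
    couplings: tuple[CouplingSpec, ...] = ()
    noise_level: float = 1.0
    min_silence_s: float = DEFAULT_MIN_SILENCE_S
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.couplings:
            if c.band_s[1] > self.duration_s / 4:
                raise ValidationError(
                    f"coupling band up to {c.band_s[1]:g}s exceeds "
                    f"duration/4 = {self.duration_s / 4:g}s"
                )


@dataclass
class SyntheticSession:
    """A generated session: recording, tiers and ground truth."""

    recording: DyadRecording
    tiers: list[SpeechInterval]
    structure: ConversationStructure
    couplings: tuple[CouplingSpec, ...]
    config: DyadSimConfig
    seed: int


# ---------------------------------------------------------------------------
# turn sequence
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, median: float, sigma: float,
               lo: float, hi: float) -> float:
    return float(np.clip(rng.lognormal(math.log(median), sigma), lo, hi))


@dataclass
class _ScheduledTurn:
    speaker: str
    units: list[tuple[float, float]]
    switch_kind: str  # "first" | "overlap" | "gap"
    backchannels: list[tuple[float, float]] = field(default_factory=list)

    @property
    def start(self) -> float:
        return self.units[0][0]

    @property
    def end(self) -> float:
        return max(e for _, e in self.units)


def generate_turn_sequence(
    cfg: DyadSimConfig, rng: np.random.Generator
) -> tuple[list[SpeechInterval], ConversationStructure]:
    """Alternating turns with pauses, overlaps, gaps and backchannels.

    Returns the raw annotation tiers (units possibly split into chunks
    separated by sub-threshold silences) and the exact expected
    conversational structure.
    """
    if cfg.duration_s < 60:
        raise ValidationError(
            f"duration must be >= 60 s for stable statistics, got {cfg.duration_s}"
        )
    tm = cfg.turns
    speakers = ("A", "B")
    turn_idx = 0
    t = 0.3
    scheduled: list[_ScheduledTurn] = []
    switch_kind = "first"
    pending_overlap = 0.0
    while True:
        speaker = speakers[turn_idx % 2]
        target = _lognormal(rng, tm.turn_median_s, tm.turn_sigma,
                            tm.turn_min_s, tm.turn_max_s)
        units: list[tuple[float, float]] = []
        u_start = t
        elapsed = 0.0
        while elapsed < target:
            dur = _lognormal(rng, tm.unit_median_s, tm.unit_sigma,
                             tm.unit_min_s, tm.unit_max_s)
            dur = min(dur, max(tm.unit_min_s, target - elapsed))
            if not units and pending_overlap > 0.0:
                # the incoming turn's first unit must outlast the overlap
                dur = max(dur, pending_overlap + 0.15)
            units.append((u_start, u_start + dur))
            elapsed += dur
            if elapsed >= target:
                break
            pause = rng.uniform(*tm.pause_range_s)
            u_start = u_start + dur + pause
            elapsed += pause
        end = units[-1][1]
        if end > cfg.duration_s - 1.0:
            # truncate: drop units beyond the session, clip the last one
            units = [(s, min(e, cfg.duration_s - 0.5)) for s, e in units
                     if s < cfg.duration_s - 1.0]
            units = [(s, e) for s, e in units if e - s > 0.3]
            if units:
                scheduled.append(_ScheduledTurn(speaker, units, switch_kind))
            break
        scheduled.append(_ScheduledTurn(speaker, units, switch_kind))
        last_dur = units[-1][1] - units[-1][0]
        # the partner's silence across this turn (span minus both overlaps)
        # must stay >= min_silence or their flanking units would merge
        span = end - units[0][0]
        ov_in = pending_overlap if switch_kind == "overlap" else 0.0
        ov_hi = min(
            tm.overlap_range_s[1],
            last_dur - 0.1,
            span - ov_in - (cfg.min_silence_s + 0.15),
        )
        if rng.uniform() < tm.overlap_prob and ov_hi >= tm.overlap_range_s[0]:
            ov = rng.uniform(tm.overlap_range_s[0], ov_hi)
            t = end - ov
            switch_kind = "overlap"
            pending_overlap = ov
        else:
            t = end + rng.uniform(*tm.gap_range_s)
            switch_kind = "gap"
            pending_overlap = 0.0
        turn_idx += 1

    # backchannels: other speaker's brief unit fully inside a middle host unit
    for st in scheduled:
        if len(st.units) < 3 or rng.uniform() >= tm.backchannel_prob:
            continue
        k = int(rng.integers(1, len(st.units) - 1))
        us, ue = st.units[k]
        bc_dur = rng.uniform(*tm.backchannel_range_s)
        margin = 0.3
        if ue - us < bc_dur + 2 * margin:
            continue
        bc_start = rng.uniform(us + margin, ue - margin - bc_dur)
        st.backchannels.append((bc_start, bc_start + bc_dur))

    return _assemble(scheduled, cfg, rng)


def _assemble(
    scheduled: list[_ScheduledTurn], cfg: DyadSimConfig, rng: np.random.Generator
) -> tuple[list[SpeechInterval], ConversationStructure]:
    tm = cfg.turns
    other = {"A": "B", "B": "A"}

    # ground-truth units (sorted by onset)
    unit_list: list[SpeechUnit] = []
    for st in scheduled:
        for s, e in st.units:
            unit_list.append(SpeechUnit(st.speaker, s, e))
        for s, e in st.backchannels:
            unit_list.append(SpeechUnit(other[st.speaker], s, e))
    unit_list.sort(key=lambda u: (u.start, u.end, u.speaker))
    index_of = {(u.speaker, u.start, u.end): i for i, u in enumerate(unit_list)}

    # ground-truth turns: scheduled turns split at backchannel onsets
    turns: list[Turn] = []
    switches: list[TurnEvent] = []
    overlaps: list[Overlap] = []
    silences: list[SilenceEvent] = []

    def emit_turn(speaker: str, units: list[tuple[float, float]]) -> Turn:
        idx = tuple(index_of[(speaker, s, e)] for s, e in units)
        t = Turn(speaker, units[0][0], max(e for _, e in units), idx)
        turns.append(t)
        return t

    for st in scheduled:
        bcs = sorted(st.backchannels)
        segments: list[list[tuple[float, float]]] = []
        cur: list[tuple[float, float]] = []
        bc_i = 0
        for u in st.units:
            while bc_i < len(bcs) and bcs[bc_i][0] <= u[0]:
                bc_i += 1
            cur.append(u)
            if bc_i < len(bcs) and u[0] < bcs[bc_i][0] < u[1]:
                segments.append(cur)
                cur = []
        if cur:
            segments.append(cur)
        # switch at the scheduled turn's own onset
        if st.switch_kind == "overlap":
            switches.append(TurnEvent("overlap_onset", st.start, st.speaker))
        elif st.switch_kind == "gap":
            switches.append(TurnEvent("turn_onset", st.start, st.speaker))
        for seg_i, seg in enumerate(segments):
            emit_turn(st.speaker, seg)
            if seg_i > 0:  # continuation after a backchannel
                switches.append(TurnEvent("turn_onset", seg[0][0], st.speaker))
        for bc in bcs:
            emit_turn(other[st.speaker], [bc])
            switches.append(TurnEvent("overlap_onset", bc[0], other[st.speaker]))
            host = next(u for u in st.units if u[0] < bc[0] < u[1])
            ia = index_of[(st.speaker, host[0], host[1])]
            ib = index_of[(other[st.speaker], bc[0], bc[1])]
            a_i, b_i = (ia, ib) if st.speaker == "A" else (ib, ia)
            overlaps.append(Overlap(bc[0], bc[1], a_i, b_i))
        # internal pauses
        for (s1, e1), (s2, e2) in zip(st.units, st.units[1:]):
            if s2 - e1 >= cfg.min_silence_s:
                silences.append(
                    SilenceEvent("pause", e1, s2, st.speaker, st.speaker)
                )

    # switch-time overlaps and gaps between consecutive scheduled turns
    for prev, nxt in zip(scheduled, scheduled[1:]):
        if nxt.switch_kind == "overlap":
            lo, hi = nxt.start, prev.end
            pl_s, pl_e = prev.units[-1]
            na, nb = nxt.units[0]
            ia = index_of[(prev.speaker, pl_s, pl_e)]
            ib = index_of[(nxt.speaker, na, nb)]
            a_i, b_i = (ia, ib) if prev.speaker == "A" else (ib, ia)
            overlaps.append(Overlap(lo, hi, a_i, b_i))
        elif nxt.switch_kind == "gap":
            if nxt.start - prev.end >= cfg.min_silence_s:
                silences.append(
                    SilenceEvent("gap", prev.end, nxt.start, prev.speaker, nxt.speaker)
                )

    turns.sort(key=lambda t: (t.start, t.end))
    overlaps.sort(key=lambda o: (o.start, o.end))
    silences.sort(key=lambda s: s.start)
    switches.sort(key=lambda e: (e.time, e.kind))

    structure = ConversationStructure(
        units=unit_list,
        silences=silences,
        turns=turns,
        overlaps=overlaps,
        switches=switches,
        min_silence=cfg.min_silence_s,
    )

    # raw tiers: split units into chunks separated by sub-threshold silences
    tiers: list[SpeechInterval] = []
    for u in unit_list:
        if u.duration > 1.2 and rng.uniform() < tm.micro_split_prob:
            pos = u.start
            while u.end - pos > 1.2:
                chunk = rng.uniform(0.4, 0.9)
                gap = rng.uniform(0.03, min(0.12, cfg.min_silence_s * 0.6))
                tiers.append(SpeechInterval(u.speaker, pos, pos + chunk))
                pos = pos + chunk + gap
            tiers.append(SpeechInterval(u.speaker, pos, u.end))
        else:
            tiers.append(SpeechInterval(u.speaker, u.start, u.end))
    tiers.sort(key=lambda iv: iv.start)
    return tiers, structure


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def syllable_pulse_train(
    onsets: Sequence[float],
    duration_s: float,
    rate: float,
    width_s: float = 0.2,
    amplitudes: Sequence[float] | None = None,
) -> np.ndarray:
    """Sum of raised-cosine bumps of ``width_s`` at the given onset times."""
    n = int(round(duration_s * rate))
    out = np.zeros(n)
    t = np.arange(n) / rate
    for k, onset in enumerate(onsets):
        amp = 1.0 if amplitudes is None else amplitudes[k]
        i0 = max(0, int(math.ceil(onset * rate)))
        i1 = min(n, int(math.floor((onset + width_s) * rate)) + 1)
        if i1 <= i0:
            continue
        phase = (t[i0:i1] - onset) / width_s
        out[i0:i1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def generate_envelopes(
    tiers: list[SpeechInterval],
    cfg: DyadSimConfig,
    rng: np.random.Generator,
) -> dict[str, UniformSeries]:
    """Voice envelope per speaker: syllable bumps inside speech intervals,
    near-zero noise floor outside."""
    em = cfg.envelope
    n = int(round(cfg.duration_s * cfg.rate))
    out: dict[str, UniformSeries] = {}
    speakers = sorted({iv.speaker for iv in tiers}) or ["A", "B"]
    for sp in ("A", "B"):
        onsets: list[float] = []
        amps: list[float] = []
        for iv in tiers:
            if iv.speaker != sp:
                continue
            k = 0
            while True:
                onset = iv.start + k / em.syllable_rate_hz + rng.uniform(
                    -em.onset_jitter_s, em.onset_jitter_s
                )
                if onset + em.syllable_s > iv.end + 0.05:
                    break
                onsets.append(max(onset, 0.0))
                amps.append(1.0 + rng.uniform(-em.amp_jitter, em.amp_jitter))
                k += 1
        env = syllable_pulse_train(onsets, cfg.duration_s, cfg.rate, em.syllable_s, amps)
        floor = em.noise_floor * (1.0 + 0.5 * np.abs(rng.standard_normal(n)))
        out[sp] = UniformSeries(env + floor, cfg.rate, 0.0, "voice_env")
    del speakers
    return out


# ---------------------------------------------------------------------------
# coupled movements
# ---------------------------------------------------------------------------

def pink_noise(
    n: int,
    rate: float,
    rng: np.random.Generator,
    f_lo: float = 0.05,
    f_hi: float = 10.0,
) -> np.ndarray:
    """Unit-variance noise with 1/f spectrum between ``f_lo`` and ``f_hi``.

    Flat below ``f_lo``; steep roll-off above ``f_hi``.
    """
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / rate)
    shape = 1.0 / np.sqrt(np.maximum(f, f_lo))
    above = f > f_hi
    shape[above] *= (f_hi / f[above]) ** 2
    spec *= shape
    spec[0] = 0.0
    x = irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandpass(x: np.ndarray, rate: float, lo_s: float, hi_s: float) -> np.ndarray:
    """Keep Fourier components with period in (lo_s, hi_s]."""
    spec = rfft(x)
    f = rfftfreq(x.size, d=1.0 / rate)
    keep = (f >= 1.0 / hi_s) & (f < 1.0 / lo_s)
    spec[~keep] = 0.0
    return irfft(spec, x.size)


def _phase_shift(x: np.ndarray, lag_deg: float) -> np.ndarray:
    """Rotate all positive-frequency components by ``-lag_deg`` so the
    original signal leads the output by ``lag_deg`` at every frequency."""
    spec = rfft(x)
    spec[1:] *= np.exp(-1j * math.radians(lag_deg))
    return irfft(spec, x.size)


def generate_coupled_movements(
    cfg: DyadSimConfig,
    rng: np.random.Generator,
    voice_envs: dict[str, UniformSeries],
) -> dict[str, UniformSeries]:
    """Head and wrist speed series with configured band couplings.

    Each movement series is 1/f background noise whose content inside a
    coupled band is replaced by a mixture ``c * shifted_driver_band +
    sqrt(1 - c^2) * own_band_noise``, giving an expected in-band
    coherence of about ``c^2`` and an exact relative phase of
    ``lag_deg`` (driver leading).
    """
    n = int(round(cfg.duration_s * cfg.rate))
    signals: dict[str, np.ndarray] = {}
    for sp in ("A", "B"):
        signals[f"{sp}.voice"] = voice_envs[sp].values
    # generation order lets movement drive movement if configured earlier
    bases = {sid: pink_noise(n, cfg.rate, rng) for sid in _MOVEMENT_IDS}
    for sid in _MOVEMENT_IDS:
        base = bases[sid]
        for c in cfg.couplings:
            if c.target != sid:
                continue
            if c.driver in signals:
                driver = signals[c.driver]
            else:
                driver = bases[c.driver]  # movement driver: use its base
            d = driver - driver.mean()
            d_b = _bandpass(d, cfg.rate, *c.band_s)
            sd = d_b.std()
            if sd == 0:
                raise ValidationError(
                    f"driver {c.driver!r} has no energy in band {c.band_s}"
                )
            d_bn = _phase_shift(d_b / sd, c.lag_deg)
            n_b = _bandpass(base, cfg.rate, *c.band_s)
            sigma_b = n_b.std()
            mixed = c.strength * d_bn + math.sqrt(1.0 - c.strength ** 2) * (
                n_b / sigma_b if sigma_b > 0 else n_b
            )
            base = base - n_b + sigma_b * mixed
        vals = 1.0 + 0.22 * cfg.noise_level * base
        signals[sid] = np.clip(vals, 0.0, None)
    label = {"head": "head_speed", "wrist": "wrist_speed"}
    return {
        sid: UniformSeries(signals[sid], cfg.rate, 0.0, label[sid.split(".")[1]])
        for sid in _MOVEMENT_IDS
    }


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def generate_session(cfg: DyadSimConfig, session_id: str | None = None) -> SyntheticSession:
    """Compose tiers, envelopes and movements into a full session.

    Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    tiers, structure = generate_turn_sequence(cfg, rng)
    envs = generate_envelopes(tiers, cfg, rng)
    moves = generate_coupled_movements(cfg, rng, envs)
    recording = DyadRecording(
        session_id=session_id or f"sim-{cfg.seed}",
        a=ParticipantSeries(moves["A.head"], moves["A.wrist"], envs["A"]),
        b=ParticipantSeries(moves["B.head"], moves["B.wrist"], envs["B"]),
        rate=cfg.rate,
    )
    return SyntheticSession(
        recording=recording,
        tiers=tiers,
        structure=structure,
        couplings=cfg.couplings,
        config=cfg,
        seed=cfg.seed,
    )


def replicate(cfg: DyadSimConfig, seeds: Sequence[int]) -> list[SyntheticSession]:
    """Generate one session per seed with otherwise identical config."""
    return [generate_session(replace(cfg, seed=s)) for s in seeds]
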