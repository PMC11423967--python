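"""Conversational-structure segmentation for a two-speaker session.

Annotated speech intervals are merged into speech units (no internal
silence of 200 ms or more), the remaining silences are classified as
pauses (same speaker on both sides) or gaps (speaker change), units are
grouped into turns, and overlaps and turn switches are extracted.

Conventions (documented, configurable where noted):

* a silence strictly shorter than ``min_silence`` merges two same-speaker
  intervals; a silence of exactly ``min_silence`` separates them;
* any onset by the other speaker terminates a turn's accretion, including
  a brief contained backchannel (backchannels and interruptions are not
  distinguished);
* the onset of an overlap and the onset of a turn each constitute a turn
  switch; a turn whose first unit starts inside the other speaker's speech
  is counted once, as an overlap switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import SpeechInterval

__all__ = [
    "SpeechUnit",
    "SilenceEvent",
    "Turn",
    "TurnEvent",
    "Overlap",
    "ConversationStructure",
    "merge_speech_units",
    "classify_silences",
    "build_turns",
    "detect_overlaps_and_switches",
    "build_structure",
    "turn_statistics",
]

DEFAULT_MIN_SILENCE_S = 0.200

#: tolerance for threshold comparisons on times given as decimal seconds
_EPS = 1e-9


@dataclass(frozen=True)
class SpeechUnit:
    """A maximal same-speaker speech stretch with no internal silence
    of ``min_silence`` or longer."""

    speaker: str
    start: float
    end: float
    source_intervals: tuple[int, ...] = ()

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SilenceEvent:
    """A classified silence: ``pause`` (same flanking speaker) or ``gap``."""

    kind: str  # "pause" | "gap"
    start: float
    end: float
    before_speaker: str
    after_speaker: str

    def __post_init__(self) -> None:
        if self.kind not in ("pause", "gap"):
            raise ValidationError(f"silence kind must be pause|gap, got {self.kind!r}")
        same = self.before_speaker == self.after_speaker
        if same != (self.kind == "pause"):
            raise ValidationError(
                f"{self.kind} between {self.before_speaker!r} and "
                f"{self.after_speaker!r} violates the pause/gap rule"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Turn:
    """A run of one speaker's units not interrupted by the other speaker."""

    speaker: str
    start: float
    end: float
    unit_indices: tuple[int, ...]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Overlap:
    """A time interval where both speakers' units intersect."""

    start: float
    end: float
    a_unit: int
    b_unit: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TurnEvent:
    """A turn switch: the onset of an overlap or the onset of a turn."""

    kind: str  # "overlap_onset" | "turn_onset"
    time: float
    incoming_speaker: str
    tie_broken: bool = False


@dataclass
class ConversationStructure:
    """Full segmentation of one dyadic session."""

    units: list[SpeechUnit]
    silences: list[SilenceEvent]
    turns: list[Turn]
    overlaps: list[Overlap]
    switches: list[TurnEvent]
    min_silence: float = DEFAULT_MIN_SILENCE_S

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize with times rounded to 3 decimals; optionally write."""
        r3 = lambda x: round(float(x), 3)  # noqa: E731
        doc = {
            "min_silence": self.min_silence,
            "units": [
                {"speaker": u.speaker, "start": r3(u.start), "end": r3(u.end)}
                for u in self.units
            ],
            "silences": [
                {
                    "kind": s.kind,
                    "start": r3(s.start),
                    "end": r3(s.end),
                    "before_speaker": s.before_speaker,
                    "after_speaker": s.after_speaker,
                }
                for s in self.silences
            ],
            "turns": [
                {
                    "speaker": t.speaker,
                    "start": r3(t.start),
                    "end": r3(t.end),
                    "unit_indices": list(t.unit_indices),
                }
                for t in self.turns
            ],
            "overlaps": [
                {"start": r3(o.start), "end": r3(o.end)} for o in self.overlaps
            ],
            "switches": [
                {
                    "kind": e.kind,
                    "time": r3(e.time),
                    "incoming_speaker": e.incoming_speaker,
                }
                for e in self.switches
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def merge_speech_units(
    intervals: list[SpeechInterval], min_silence: float = DEFAULT_MIN_SILENCE_S
) -> list[SpeechUnit]:
    """Merge same-speaker intervals separated by silence < ``min_silence``.

    Merging is transitive; output is sorted by start time.  Overlapping
    same-speaker intervals are an annotation defect and raise
    :class:`ValidationError`.
    """
    if not min_silence > 0:
        raise ValueError(f"min_silence must be > 0, got {min_silence}")
    by_speaker: dict[str, list[tuple[int, SpeechInterval]]] = {}
    for idx, iv in enumerate(intervals):
        by_speaker.setdefault(iv.speaker, []).append((idx, iv))

    units: list[SpeechUnit] = []
    for speaker, items in by_speaker.items():
        items.sort(key=lambda t: (t[1].start, t[1].end))
        cur_start = cur_end = None
        cur_src: list[int] = []
        for idx, iv in items:
            if cur_end is None:
                cur_start, cur_end, cur_src = iv.start, iv.end, [idx]
                continue
            if iv.start < cur_end:
                raise ValidationError(
                    f"overlapping intervals for speaker {speaker!r} at "
                    f"{iv.start:g}s (previous ends {cur_end:g}s)"
                )
            # strict "< min_silence" with a small tolerance so that
            # silences of exactly min_silence written as decimals do not
            # merge through floating-point rounding
            if iv.start - cur_end < min_silence - _EPS:
                cur_end = iv.end
                cur_src.append(idx)
            else:
                units.append(SpeechUnit(speaker, cur_start, cur_end, tuple(cur_src)))
                cur_start, cur_end, cur_src = iv.start, iv.end, [idx]
        if cur_end is not None:
            units.append(SpeechUnit(speaker, cur_start, cur_end, tuple(cur_src)))
    units.sort(key=lambda u: (u.start, u.end, u.speaker))
    return units


def classify_silences(
    units: list[SpeechUnit], min_silence: float = DEFAULT_MIN_SILENCE_S
) -> list[SilenceEvent]:
    """Classify silences of at least ``min_silence`` between consecutive units.

    A silence is a maximal interval, inside the conversation's span, in
    which neither speaker has a unit.  It is a *pause* if flanked by the
    same speaker and a *gap* otherwise.  Shorter inter-speaker silences are
    left unclassified (same-speaker ones cannot occur after merging).
    """
    if not units:
        return []
    events: list[SilenceEvent] = []
    by_start = sorted(units, key=lambda u: (u.start, u.end))
    # sweep over the union of unit intervals
    frontier_end = by_start[0].end
    frontier_unit = by_start[0]
    for u in by_start[1:]:
        if u.start > frontier_end:
            dur = u.start - frontier_end
            if dur >= min_silence - _EPS:
                events.append(
                    SilenceEvent(
                        kind=(
                            "pause"
                            if frontier_unit.speaker == u.speaker
                            else "gap"
                        ),
                        start=frontier_end,
                        end=u.start,
                        before_speaker=frontier_unit.speaker,
                        after_speaker=u.speaker,
                    )
                )
        if u.end > frontier_end or (
            u.end == frontier_end and u.start > frontier_unit.start
        ):
            frontier_unit = u
        frontier_end = max(frontier_end, u.end)
    return events


def build_turns(
    units: list[SpeechUnit], silences: list[SilenceEvent] | None = None
) -> list[Turn]:
    """Group units into turns.

    Processing units in onset order, a maximal run of same-speaker onsets
    forms one turn: any other-speaker onset (an overlapping unit or a unit
    following a gap) terminates accretion.  Every unit belongs to exactly
    one turn.
    """
    order = sorted(range(len(units)), key=lambda i: (units[i].start, units[i].end))
    turns: list[Turn] = []
    run: list[int] = []
    for i in order:
        if run and units[i].speaker != units[run[-1]].speaker:
            turns.append(_close_turn(units, run))
            run = []
        run.append(i)
    if run:
        turns.append(_close_turn(units, run))
    return turns


def _close_turn(units: list[SpeechUnit], run: list[int]) -> Turn:
    return Turn(
        speaker=units[run[0]].speaker,
        start=units[run[0]].start,
        end=max(units[i].end for i in run),
        unit_indices=tuple(run),
    )


def detect_overlaps_and_switches(
    units: list[SpeechUnit], turns: list[Turn]
) -> tuple[list[Overlap], list[TurnEvent]]:
    """Overlaps (intersections of the two speakers' units) and turn switches.

    Switches are the onsets of overlaps (incoming = later-starting speaker;
    exact ties broken by speaker label order and flagged) plus the onsets
    of turns that follow a different-speaker turn and do not themselves
    begin inside the other speaker's speech (those are already counted as
    overlap onsets).
    """
    speakers = sorted({u.speaker for u in units})
    overlaps: list[Overlap] = []
    switches: list[TurnEvent] = []
    if len(speakers) == 2:
        sa, sb = speakers
        a_units = [(i, u) for i, u in enumerate(units) if u.speaker == sa]
        b_units = [(i, u) for i, u in enumerate(units) if u.speaker == sb]
        for ia, ua in a_units:
            for ib, ub in b_units:
                lo = max(ua.start, ub.start)
                hi = min(ua.end, ub.end)
                if hi > lo:
                    overlaps.append(Overlap(lo, hi, ia, ib))
                    if ua.start == ub.start:
                        incoming, tie = ub.speaker, True  # label-order tie-break
                    else:
                        incoming = ua.speaker if ua.start > ub.start else ub.speaker
                        tie = False
                    switches.append(
                        TurnEvent("overlap_onset", lo, incoming, tie_broken=tie)
                    )
        overlaps.sort(key=lambda o: (o.start, o.end))

    def inside_other(t: Turn) -> bool:
        return any(
            u.speaker != t.speaker and u.start < t.start < u.end for u in units
        )

    prev: Turn | None = None
    for t in sorted(turns, key=lambda t: (t.start, t.end)):
        if prev is not None and prev.speaker != t.speaker and not inside_other(t):
            switches.append(TurnEvent("turn_onset", t.start, t.speaker))
        prev = t
    switches.sort(key=lambda e: (e.time, e.kind))
    return overlaps, switches


def build_structure(
    intervals: list[SpeechInterval], min_silence: float = DEFAULT_MIN_SILENCE_S
) -> ConversationStructure:
    """Full segmentation: intervals → units → silences → turns → switches."""
    units = merge_speech_units(intervals, min_silence)
    silences = classify_silences(units, min_silence)
    turns = build_turns(units, silences)
    overlaps, switches = detect_overlaps_and_switches(units, turns)
    return ConversationStructure(
        units=units,
        silences=silences,
        turns=turns,
        overlaps=overlaps,
        switches=switches,
        min_silence=min_silence,
    )


#: turn-duration histogram bin edges in seconds: (0,10], (10,20], (20,30], >30
TURN_DURATION_EDGES_S = (0.0, 10.0, 20.0, 30.0)


@dataclass
class TurnStatistics:
    """Summary statistics of a :class:`ConversationStructure`."""

    n_turns: int
    n_switches: int
    n_overlaps: int
    duration_bins: tuple[float, ...] | None  # proportions, None if no turns
    overlap_switch_share: float | None
    mean_turn_duration: float | None
    median_turn_duration: float | None
    empty: bool = False


def turn_statistics(structure: ConversationStructure) -> TurnStatistics:
    """Turn-duration histogram, overlap share of switches, counts.

    With zero turns, proportions are reported as missing (``None``), not 0.
    """
    durations = np.array([t.duration for t in structure.turns])
    n_turns = durations.size
    n_switches = len(structure.switches)
    n_overlap_sw = sum(1 for e in structure.switches if e.kind == "overlap_onset")
    if n_turns == 0:
        return TurnStatistics(
            n_turns=0,
            n_switches=n_switches,
            n_overlaps=len(structure.overlaps),
            duration_bins=None,
            overlap_switch_share=None,
            mean_turn_duration=None,
            median_turn_duration=None,
            empty=True,
        )
    e = TURN_DURATION_EDGES_S
    bins = (
        float(np.mean((durations > e[0]) & (durations <= e[1]))),
        float(np.mean((durations > e[1]) & (durations <= e[2]))),
        float(np.mean((durations > e[2]) & (durations <= e[3]))),
        float(np.mean(durations > e[3])),
    )
    return TurnStatistics(
        n_turns=int(n_turns),
        n_switches=n_switches,
        n_overlaps=len(structure.overlaps),
        duration_bins=bins,
        overlap_switch_share=(
            n_overlap_sw / n_switches if n_switches else None
        ),
        mean_turn_duration=float(durations.mean()),
        median_turn_duration=float(np.median(durations)),
    )
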