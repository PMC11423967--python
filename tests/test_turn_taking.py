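"""Turn-taking segmentation: unit merging, silences, turns, switches.

The brute-force oracle below re-derives every quantity directly from the
definitions with quadratic scans, independently of the module's sweep
implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync.errors import ValidationError
from dyadsync.io_formats import SpeechInterval
from dyadsync.turn_taking import (
    build_structure,
    build_turns,
    classify_silences,
    detect_overlaps_and_switches,
    merge_speech_units,
    turn_statistics,
)


def iv(sp, a, b):
    return SpeechInterval(sp, a, b)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def oracle_units(intervals, min_silence):
    """Repeated pairwise merging until fixpoint."""
    per = {}
    for i in intervals:
        per.setdefault(i.speaker, []).append([i.start, i.end])
    out = []
    for sp, items in per.items():
        items = sorted(items)
        changed = True
        while changed:
            changed = False
            for k in range(len(items) - 1):
                if items[k + 1][0] - items[k][1] < min_silence:
                    items[k] = [items[k][0], max(items[k][1], items[k + 1][1])]
                    del items[k + 1]
                    changed = True
                    break
        out.extend((sp, a, b) for a, b in items)
    return sorted(out, key=lambda u: (u[1], u[2], u[0]))


def oracle_turns(units):
    """Group by literal definition: a unit extends the current turn iff no
    other-speaker unit onset lies in [previous onset, this onset)."""
    units = sorted(units, key=lambda u: (u[1], u[2]))
    turns = []
    for sp, a, b in units:
        if turns and turns[-1][0] == sp:
            prev_onset = turns[-1][2][-1][0]
            interrupted = any(
                o_sp != sp and prev_onset <= o_a < a
                for o_sp, o_a, _ in units
            )
            if not interrupted:
                turns[-1][2].append((a, b))
                continue
        turns.append([sp, a, [(a, b)]])
    return [
        (sp, onsets[0][0], max(e for _, e in onsets))
        for sp, _, onsets in turns
    ]


def oracle_overlaps(units):
    out = []
    for sa, a1, a2 in units:
        for sb, b1, b2 in units:
            if sa < sb:
                lo, hi = max(a1, b1), min(a2, b2)
                if hi > lo:
                    out.append((lo, hi))
    return sorted(out)


def oracle_silences(units, min_silence):
    """Quadratic: every (unit end, later unit start) pair with nothing in
    between is a candidate silence; intersection is checked exactly."""
    events = {}
    for _, _, e in units:
        for _, s, _ in units:
            if s <= e or s - e < min_silence - 1e-9:
                continue
            if any(a < s and b > e for _, a, b in units):
                continue
            before_sp = max(
                (u for u in units if u[2] == e), key=lambda u: u[1]
            )[0]
            after_sp = min(
                (u for u in units if u[1] == s), key=lambda u: u[2]
            )[0]
            kind = "pause" if before_sp == after_sp else "gap"
            events[(e, s)] = (kind, e, s)
    return sorted(events.values(), key=lambda ev: ev[1])


def random_session(rng, n_units=12, backchannels=True):
    """Random two-speaker intervals with plausible structure."""
    intervals = []
    t = {"A": 0.0, "B": float(rng.uniform(0, 2))}
    for _ in range(n_units):
        sp = "A" if rng.uniform() < 0.5 else "B"
        start = t[sp] + float(rng.uniform(0.05, 1.5))
        dur = float(rng.uniform(0.1, 3.0))
        intervals.append(iv(sp, start, start + dur))
        t[sp] = start + dur
    return intervals


# ---------------------------------------------------------------------------
# merge_speech_units
# ---------------------------------------------------------------------------

class TestMergeSpeechUnits:
    def test_short_silence_merges(self):
        units = merge_speech_units([iv("A", 0, 1.0), iv("A", 1.15, 2.0)], 0.2)
        assert len(units) == 1
        assert (units[0].start, units[0].end) == (0, 2.0)

    def test_long_silence_separates(self):
        units = merge_speech_units([iv("A", 0, 1.0), iv("A", 1.25, 2.0)], 0.2)
        assert len(units) == 2

    def test_boundary_silence_does_not_merge(self):
        units = merge_speech_units([iv("A", 0, 1.0), iv("A", 1.2, 2.0)], 0.2)
        assert len(units) == 2

    def test_single_interval(self):
        (u,) = merge_speech_units([iv("A", 1.0, 2.5)], 0.2)
        assert (u.speaker, u.start, u.end) == ("A", 1.0, 2.5)
        assert u.source_intervals == (0,)

    def test_overlapping_same_speaker_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            merge_speech_units([iv("A", 0, 1.0), iv("A", 0.5, 2.0)], 0.2)

    def test_transitive_merge(self):
        units = merge_speech_units(
            [iv("A", 0, 1), iv("A", 1.1, 2), iv("A", 2.1, 3)], 0.2
        )
        assert len(units) == 1
        assert units[0].source_intervals == (0, 1, 2)

    def test_idempotent(self, rng):
        for _ in range(20):
            intervals = random_session(rng)
            units = merge_speech_units(intervals, 0.2)
            as_intervals = [iv(u.speaker, u.start, u.end) for u in units]
            again = merge_speech_units(as_intervals, 0.2)
            assert [(u.speaker, u.start, u.end) for u in units] == [
                (u.speaker, u.start, u.end) for u in again
            ]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        intervals = random_session(rng, n_units=8)
        counts = [
            len(merge_speech_units(intervals, ms))
            for ms in (0.05, 0.2, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_matches_oracle(self, rng):
        for _ in range(50):
            intervals = random_session(rng)
            got = [
                (u.speaker, u.start, u.end)
                for u in merge_speech_units(intervals, 0.2)
            ]
            assert got == oracle_units(intervals, 0.2)


# ---------------------------------------------------------------------------
# classify_silences
# ---------------------------------------------------------------------------

class TestClassifySilences:
    def test_pause(self):
        units = merge_speech_units([iv("A", 0, 2.0), iv("A", 2.5, 3.0)], 0.2)
        (s,) = classify_silences(units, 0.2)
        assert (s.kind, s.start, s.end) == ("pause", 2.0, 2.5)

    def test_gap(self):
        units = merge_speech_units([iv("A", 0, 2.0), iv("B", 2.4, 3.0)], 0.2)
        (s,) = classify_silences(units, 0.2)
        assert (s.kind, s.start, s.end) == ("gap", 2.0, 2.4)

    def test_seamless_alternation_no_events(self):
        units = merge_speech_units(
            [iv("A", 0, 1.0), iv("B", 1.0, 2.0), iv("A", 2.0, 3.0)], 0.2
        )
        assert classify_silences(units, 0.2) == []

    def test_short_interspeaker_silence_unclassified(self):
        units = merge_speech_units([iv("A", 0, 2.0), iv("B", 2.1, 3.0)], 0.2)
        assert classify_silences(units, 0.2) == []

    def test_silence_covered_by_other_speaker_becomes_gap(self):
        # A pauses 2.0-3.0 but B speaks 1.5-2.8: the actual silence is
        # (2.8, 3.0), flanked by B then A, hence a gap rather than a pause
        units = merge_speech_units(
            [iv("A", 0, 2.0), iv("A", 3.0, 4.0), iv("B", 1.5, 2.8)], 0.2
        )
        (s,) = classify_silences(units, 0.2)
        assert (s.kind, s.before_speaker, s.after_speaker) == ("gap", "B", "A")
        assert (s.start, s.end) == (2.8, 3.0)


# ---------------------------------------------------------------------------
# build_turns / overlaps / switches
# ---------------------------------------------------------------------------

class TestBuildTurns:
    def test_pause_joined_when_other_silent(self):
        units = merge_speech_units([iv("A", 0, 2.0), iv("A", 2.5, 4.0)], 0.2)
        turns = build_turns(units)
        assert len(turns) == 1
        assert (turns[0].start, turns[0].end) == (0, 4.0)

    def test_backchannel_splits_turn(self):
        units = merge_speech_units(
            [iv("A", 0, 2.0), iv("A", 2.5, 4.0), iv("B", 2.1, 2.3)], 0.2
        )
        turns = build_turns(units)
        speakers = [t.speaker for t in turns]
        assert speakers == ["A", "B", "A"]

    def test_strict_alternation(self):
        intervals = []
        for k in range(5):
            intervals.append(iv("A", 2 * k, 2 * k + 0.8))
            intervals.append(iv("B", 2 * k + 1, 2 * k + 1.8))
        turns = build_turns(merge_speech_units(intervals, 0.2))
        assert len(turns) == 10

    def test_every_unit_in_exactly_one_turn(self, rng):
        for _ in range(30):
            units = merge_speech_units(random_session(rng), 0.2)
            turns = build_turns(units)
            assigned = sorted(i for t in turns for i in t.unit_indices)
            assert assigned == list(range(len(units)))

    def test_turn_durations_cover_units(self, rng):
        units = merge_speech_units(random_session(rng), 0.2)
        turns = build_turns(units)
        per_speaker_units = {}
        for u in units:
            per_speaker_units[u.speaker] = per_speaker_units.get(u.speaker, 0) + u.duration
        per_speaker_turns = {}
        for t in turns:
            per_speaker_turns[t.speaker] = per_speaker_turns.get(t.speaker, 0) + t.duration
        for sp, total in per_speaker_units.items():
            assert per_speaker_turns[sp] >= total - 1e-9


class TestOverlapsAndSwitches:
    def test_simple_overlap(self):
        units = merge_speech_units([iv("A", 0, 2.0), iv("B", 1.5, 3.0)], 0.2)
        turns = build_turns(units)
        overlaps, switches = detect_overlaps_and_switches(units, turns)
        assert [(o.start, o.end) for o in overlaps] == [(1.5, 2.0)]
        assert switches[0].kind == "overlap_onset"
        assert switches[0].time == 1.5
        assert switches[0].incoming_speaker == "B"

    def test_no_intersection_only_turn_onsets(self):
        units = merge_speech_units(
            [iv("A", 0, 1.0), iv("B", 1.5, 2.0), iv("A", 2.5, 3.0)], 0.2
        )
        turns = build_turns(units)
        overlaps, switches = detect_overlaps_and_switches(units, turns)
        assert overlaps == []
        assert [e.kind for e in switches] == ["turn_onset", "turn_onset"]
        assert [e.time for e in switches] == [1.5, 2.5]

    def test_contained_backchannel_counts_as_overlap(self):
        units = merge_speech_units([iv("A", 0, 5.0), iv("B", 2.0, 2.4)], 0.2)
        turns = build_turns(units)
        overlaps, switches = detect_overlaps_and_switches(units, turns)
        assert [(o.start, o.end) for o in overlaps] == [(2.0, 2.4)]
        assert any(e.kind == "overlap_onset" and e.time == 2.0 for e in switches)

    def test_identical_onset_tie_flagged(self):
        units = merge_speech_units([iv("A", 1.0, 2.0), iv("B", 1.0, 1.5)], 0.2)
        turns = build_turns(units)
        overlaps, switches = detect_overlaps_and_switches(units, turns)
        ov_events = [e for e in switches if e.kind == "overlap_onset"]
        assert ov_events[0].tie_broken

    def test_matches_oracle(self, rng):
        for _ in range(100):
            intervals = random_session(rng)
            st_ = build_structure(intervals, 0.2)
            got_turns = [(t.speaker, t.start, t.end) for t in st_.turns]
            units3 = [(u.speaker, u.start, u.end) for u in st_.units]
            assert got_turns == oracle_turns(units3)
            got_ov = sorted((o.start, o.end) for o in st_.overlaps)
            assert got_ov == oracle_overlaps(units3)
            got_sil = [(s.kind, s.start, s.end) for s in st_.silences]
            assert got_sil == oracle_silences(units3, 0.2)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestTurnStatistics:
    def _structure_with_turns(self, durations):
        intervals = []
        t = 0.0
        for k, d in enumerate(durations):
            sp = "AB"[k % 2]
            intervals.append(iv(sp, t, t + d))
            t += d + 0.5
        return build_structure(intervals, 0.2)

    def test_duration_bins(self):
        st_ = self._structure_with_turns([5, 8, 15, 25])
        stats = turn_statistics(st_)
        assert stats.duration_bins == (0.5, 0.25, 0.25, 0.0)

    def test_overlap_share_70_30(self):
        intervals = []
        t = 0.0
        # 11 turns -> 10 switches; 7 overlaps, 3 clean turn onsets
        for k in range(11):
            sp = "AB"[k % 2]
            start = t - 0.3 if 0 < k <= 7 else t + (0.5 if k else 0.0)
            intervals.append(iv(sp, start, start + 2.0))
            t = start + 2.0
        st_ = build_structure(intervals, 0.2)
        stats = turn_statistics(st_)
        assert stats.n_switches == 10
        assert stats.overlap_switch_share == pytest.approx(0.7)

    def test_empty_structure_flag(self):
        st_ = build_structure([], 0.2)
        stats = turn_statistics(st_)
        assert stats.empty
        assert stats.duration_bins is None
        assert stats.overlap_switch_share is None

    def test_recount_oracle(self, rng):
        for _ in range(200):
            st_ = build_structure(random_session(rng, n_units=10), 0.2)
            stats = turn_statistics(st_)
            durs = [t.end - t.start for t in st_.turns]
            bins = (
                sum(1 for d in durs if 0 < d <= 10) / len(durs),
                sum(1 for d in durs if 10 < d <= 20) / len(durs),
                sum(1 for d in durs if 20 < d <= 30) / len(durs),
                sum(1 for d in durs if d > 30) / len(durs),
            )
            assert stats.duration_bins == bins
            assert stats.mean_turn_duration == pytest.approx(np.mean(durs))
            assert stats.median_turn_duration == pytest.approx(np.median(durs))
            n_ov = sum(1 for e in st_.switches if e.kind == "overlap_onset")
            if st_.switches:
                assert stats.overlap_switch_share == n_ov / len(st_.switches)


def test_structure_json_roundtrip_fields(tmp_path, rng):
    st_ = build_structure(random_session(rng), 0.2)
    path = tmp_path / "structure.json"
    st_.to_json(path)
    import json

    doc = json.loads(path.read_text())
    assert set(doc) == {
        "min_silence", "units", "silences", "turns", "overlaps", "switches"
    }
    assert len(doc["units"]) == len(st_.units)
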