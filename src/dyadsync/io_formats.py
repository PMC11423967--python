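"""Readers and writers for the pipeline's standard formats.

Supported inputs: BVH motion files (HIERARCHY/MOTION dialect), WAV audio
(integer PCM or float), and speech-interval tiers as tab-separated text
(``speaker<TAB>start<TAB>end`` in seconds).  Outputs: per-band summary
tables and plain-text series files, both TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import ParseError, ValidationError
from .series import UniformSeries

__all__ = [
    "SkeletonAnimation",
    "MarkerTrajectory",
    "SpeechInterval",
    "read_bvh",
    "world_positions",
    "read_audio",
    "read_tiers",
    "write_tiers",
    "write_band_table",
    "read_band_table",
    "write_series",
    "read_series",
]

_POSITION_CHANNELS = {"Xposition", "Yposition", "Zposition"}
_ROTATION_CHANNELS = {"Xrotation", "Yrotation", "Zrotation"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SkeletonAnimation:
    """Parsed content of a BVH file.

    ``joints`` is ordered root-first; every non-root joint's parent appears
    earlier in the list.  ``frames`` has one row per motion frame and one
    column per declared channel, in file order.
    """

    joints: list[str]
    parent: dict[str, str | None]
    offsets: dict[str, np.ndarray]
    channels: dict[str, list[str]]
    frame_time: float
    frames: np.ndarray
    end_offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_time > 0:
            raise ValidationError(f"frame_time must be > 0, got {self.frame_time}")
        seen: set[str] = set()
        for j in self.joints:
            p = self.parent.get(j)
            if p is None:
                pass
            elif p not in seen:
                raise ValidationError(
                    f"joint {j!r} has parent {p!r} not appearing earlier"
                )
            seen.add(j)
        n_channels = sum(len(c) for c in self.channels.values())
        if self.frames.ndim != 2 or self.frames.shape[1] != n_channels:
            raise ValidationError(
                f"frame data has {self.frames.shape[1] if self.frames.ndim == 2 else '?'} "
                f"columns, header declares {n_channels} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def rate(self) -> float:
        return 1.0 / self.frame_time

    def channel_slice(self, joint: str) -> slice:
        """Column slice of ``frames`` holding this joint's channels."""
        start = 0
        for j in self.joints:
            n = len(self.channels[j])
            if j == joint:
                return slice(start, start + n)
            start += n
        raise KeyError(joint)

    def chain(self, joint: str) -> list[str]:
        """Ancestor chain root → ``joint`` inclusive."""
        chain: list[str] = []
        cur: str | None = joint
        while cur is not None:
            chain.append(cur)
            cur = self.parent[cur]
        return chain[::-1]


@dataclass
class MarkerTrajectory:
    """World-coordinate positions of a single joint over time."""

    joint: str
    positions: np.ndarray  # (n_frames, 3)
    rate: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"positions must be (n, 3), got {self.positions.shape}"
            )
        if not self.rate > 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions contain non-finite values")


@dataclass(frozen=True, order=True)
class SpeechInterval:
    """One annotated speaking interval of one speaker."""

    speaker: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.end > self.start >= 0):
            raise ValidationError(
                f"speech interval requires end > start >= 0, got "
                f"[{self.start}, {self.end}] for speaker {self.speaker!r}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# BVH
# ---------------------------------------------------------------------------

class _Cursor:
    """Line cursor over the BVH token stream, for error reporting."""

    def __init__(self, lines: Sequence[str]):
        self.lines = lines
        self.i = 0

    def peek(self) -> list[str] | None:
        while self.i < len(self.lines):
            toks = self.lines[self.i].split()
            if toks:
                return toks
            self.i += 1
        return None

    def next(self) -> list[str]:
        toks = self.peek()
        if toks is None:
            raise ParseError(f"line {len(self.lines)}: unexpected end of file")
        self.i += 1
        return toks

    @property
    def lineno(self) -> int:
        return self.i  # 1-based number of the line just consumed


def read_bvh(path: str | Path) -> SkeletonAnimation:
    """Parse a BVH file into a :class:`SkeletonAnimation`.

    Raises :class:`ParseError` (naming the offending line number) on a
    malformed header, a channel-count mismatch, or fewer data rows than the
    declared frame count.
    """
    text = Path(path).read_text()
    cur = _Cursor(text.splitlines())

    toks = cur.next()
    if toks[0].upper() != "HIERARCHY":
        raise ParseError(f"line {cur.lineno}: expected HIERARCHY, got {toks[0]!r}")

    joints: list[str] = []
    parent: dict[str, str | None] = {}
    offsets: dict[str, np.ndarray] = {}
    channels: dict[str, list[str]] = {}
    end_offsets: dict[str, np.ndarray] = {}

    def parse_joint(kind_toks: list[str], parent_name: str | None) -> None:
        kind = kind_toks[0].upper()
        if kind not in ("ROOT", "JOINT"):
            raise ParseError(
                f"line {cur.lineno}: expected ROOT or JOINT, got {kind_toks[0]!r}"
            )
        if len(kind_toks) < 2:
            raise ParseError(f"line {cur.lineno}: {kind} without a name")
        name = " ".join(kind_toks[1:])
        if name in parent:
            raise ParseError(f"line {cur.lineno}: duplicate joint name {name!r}")
        joints.append(name)
        parent[name] = parent_name

        if cur.next()[0] != "{":
            raise ParseError(f"line {cur.lineno}: expected '{{' after {name!r}")
        toks = cur.next()
        if toks[0].upper() != "OFFSET" or len(toks) != 4:
            raise ParseError(f"line {cur.lineno}: expected 'OFFSET x y z'")
        try:
            offsets[name] = np.array([float(v) for v in toks[1:]])
        except ValueError:
            raise ParseError(f"line {cur.lineno}: non-numeric OFFSET") from None
        toks = cur.next()
        if toks[0].upper() != "CHANNELS":
            raise ParseError(f"line {cur.lineno}: expected CHANNELS")
        try:
            n = int(toks[1])
        except (IndexError, ValueError):
            raise ParseError(f"line {cur.lineno}: CHANNELS needs a count") from None
        labels = toks[2:]
        if len(labels) != n:
            raise ParseError(
                f"line {cur.lineno}: CHANNELS declares {n} but lists {len(labels)}"
            )
        bad = [c for c in labels if c not in _POSITION_CHANNELS | _ROTATION_CHANNELS]
        if bad:
            raise ParseError(f"line {cur.lineno}: unknown channel(s) {bad}")
        channels[name] = labels

        while True:
            toks = cur.next()
            head = toks[0].upper()
            if head == "}":
                return
            if head in ("ROOT", "JOINT"):
                parse_joint(toks, name)
            elif head == "END" or head == "END SITE":
                # "End Site" block: brace, OFFSET, brace
                if cur.next()[0] != "{":
                    raise ParseError(f"line {cur.lineno}: expected '{{' after End Site")
                otoks = cur.next()
                if otoks[0].upper() != "OFFSET" or len(otoks) != 4:
                    raise ParseError(f"line {cur.lineno}: End Site needs 'OFFSET x y z'")
                end_offsets[name] = np.array([float(v) for v in otoks[1:]])
                if cur.next()[0] != "}":
                    raise ParseError(f"line {cur.lineno}: unclosed End Site")
            else:
                raise ParseError(
                    f"line {cur.lineno}: unexpected token {toks[0]!r} in joint block"
                )

    parse_joint(cur.next(), None)

    toks = cur.next()
    if toks[0].upper() != "MOTION":
        raise ParseError(f"line {cur.lineno}: expected MOTION, got {toks[0]!r}")
    toks = cur.next()
    if toks[0].rstrip(":").upper() != "FRAMES":
        raise ParseError(f"line {cur.lineno}: expected 'Frames:'")
    try:
        n_frames = int(toks[-1])
    except ValueError:
        raise ParseError(f"line {cur.lineno}: non-integer frame count") from None
    toks = cur.next()
    if toks[0].upper() != "FRAME" or not toks[1].rstrip(":").upper().startswith("TIME"):
        raise ParseError(f"line {cur.lineno}: expected 'Frame Time:'")
    try:
        frame_time = float(toks[-1])
    except ValueError:
        raise ParseError(f"line {cur.lineno}: non-numeric frame time") from None

    n_channels = sum(len(c) for c in channels.values())
    rows = []
    for k in range(n_frames):
        toks = cur.peek()
        if toks is None:
            raise ParseError(
                f"line {len(cur.lines)}: declared {n_frames} frames but found {k}"
            )
        cur.next()
        if len(toks) != n_channels:
            raise ParseError(
                f"line {cur.lineno}: frame row has {len(toks)} values, "
                f"header declares {n_channels} channels"
            )
        try:
            rows.append([float(v) for v in toks])
        except ValueError:
            raise ParseError(f"line {cur.lineno}: non-numeric frame value") from None

    frames = np.asarray(rows, dtype=np.float64).reshape(n_frames, n_channels)
    return SkeletonAnimation(
        joints=joints,
        parent=parent,
        offsets=offsets,
        channels=channels,
        frame_time=frame_time,
        frames=frames,
        end_offsets=end_offsets,
    )


def _axis_rotation(axis: str, degrees: np.ndarray) -> np.ndarray:
    """(n, 3, 3) right-handed rotation matrices about a principal axis."""
    t = np.deg2rad(degrees)
    c, s = np.cos(t), np.sin(t)
    n = t.shape[0]
    R = np.zeros((n, 3, 3))
    if axis == "X":
        R[:, 0, 0] = 1
        R[:, 1, 1], R[:, 1, 2] = c, -s
        R[:, 2, 1], R[:, 2, 2] = s, c
    elif axis == "Y":
        R[:, 0, 0], R[:, 0, 2] = c, s
        R[:, 1, 1] = 1
        R[:, 2, 0], R[:, 2, 2] = -s, c
    elif axis == "Z":
        R[:, 0, 0], R[:, 0, 1] = c, -s
        R[:, 1, 0], R[:, 1, 1] = s, c
        R[:, 2, 2] = 1
    else:  # pragma: no cover
        raise ValueError(axis)
    return R


def world_positions(anim: SkeletonAnimation, joint: str) -> MarkerTrajectory:
    """Forward kinematics: world position of ``joint`` at every frame.

    Transforms are composed root-to-joint; each joint contributes its offset
    plus any position channels, then its Euler rotations applied in the
    order declared on its CHANNELS line (right-handed, degrees).
    """
    if joint not in anim.parent:
        raise KeyError(
            f"unknown joint {joint!r}; available: {', '.join(anim.joints)}"
        )
    n = anim.n_frames
    pos = np.zeros((n, 3))
    rot = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    for name in anim.chain(joint):
        sl = anim.channel_slice(name)
        vals = anim.frames[:, sl]
        local_t = np.broadcast_to(anim.offsets[name], (n, 3)).copy()
        local_r = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        for k, ch in enumerate(anim.channels[name]):
            if ch in _POSITION_CHANNELS:
                local_t[:, "XYZ".index(ch[0])] += vals[:, k]
            else:
                local_r = np.einsum(
                    "nij,njk->nik", local_r, _axis_rotation(ch[0], vals[:, k])
                )
        pos = pos + np.einsum("nij,nj->ni", rot, local_t)
        rot = np.einsum("nij,njk->nik", rot, local_r)
    return MarkerTrajectory(joint=joint, positions=pos, rate=anim.rate)


def find_joint(anim: SkeletonAnimation, pattern: str) -> str:
    """Return the first joint whose name contains ``pattern`` (case-insensitive)."""
    pat = pattern.lower()
    for j in anim.joints:
        if pat in j.lower():
            return j
    raise KeyError(
        f"no joint matching {pattern!r}; available: {', '.join(anim.joints)}"
    )


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def read_audio(path: str | Path, channel: int = 0) -> UniformSeries:
    """Read one channel of a WAV file as a ``raw_audio`` series.

    Integer PCM is rescaled to [-1, 1] by the type's full scale
    (e.g. int16 / 32768); float data is returned as stored.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        if channel != 0:
            raise ValueError(f"mono file has only channel 0, asked for {channel}")
        values = data
    else:
        if not (0 <= channel < data.shape[1]):
            raise ValueError(
                f"channel {channel} out of range for {data.shape[1]}-channel file"
            )
        values = data[:, channel]

    if values.dtype == np.int16:
        out = values / 32768.0
    elif values.dtype == np.int32:
        out = values / 2147483648.0
    elif values.dtype == np.uint8:
        out = (values.astype(np.float64) - 128.0) / 128.0
    elif values.dtype.kind == "f":
        out = values.astype(np.float64)
    else:
        raise ParseError(f"unsupported WAV sample format {values.dtype}")
    return UniformSeries(out, rate=float(rate), label="raw_audio")


# ---------------------------------------------------------------------------
# speech tiers
# ---------------------------------------------------------------------------

def read_tiers(path: str | Path) -> list[SpeechInterval]:
    """Read a speech-tier TSV (header ``speaker	start	end``, seconds).

    Returns intervals sorted by start (stable, hence also by start within
    each speaker).  Rows with ``end <= start`` or negative times raise
    :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["speaker", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ParseError(
            f"tier file must have columns {required}, got {list(df.columns)}"
        )
    intervals = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            intervals.append(
                SpeechInterval(str(row.speaker), float(row.start), float(row.end))
            )
        except ValidationError as e:
            raise ValidationError(f"row {i + 2}: {e}") from None
    intervals.sort(key=lambda iv: iv.start)
    return intervals


def write_tiers(intervals: Iterable[SpeechInterval], path: str | Path) -> None:
    """Write intervals as a tier TSV (inverse of :func:`read_tiers`)."""
    df = pd.DataFrame(
        [(iv.speaker, iv.start, iv.end) for iv in intervals],
        columns=["speaker", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


# ---------------------------------------------------------------------------
# band tables
# ---------------------------------------------------------------------------

_BAND_COLUMNS = [
    "pair",
    "level",
    "modality_class",
    "band_lo_s",
    "band_hi_s",
    "mean_coherence",
    "circ_mean_phase_deg",
    "resultant_length",
    "n_valid_bins",
]


def write_band_table(summaries, path: str | Path) -> None:
    """Write a list of :class:`~dyadsync.wavelet_sync.BandSummary` as TSV.

    One row per (pair, band); numeric columns at 6 significant digits so
    the table round-trips losslessly at that precision.
    """
    rows = []
    for summary in summaries:
        for b in summary.bands:
            rows.append(
                (
                    summary.pair,
                    summary.level,
                    summary.modality_class,
                    b.lo,
                    b.hi,
                    b.mean_coherence,
                    b.circ_mean_phase_deg,
                    b.resultant_length,
                    b.n_valid_bins,
                )
            )
    df = pd.DataFrame(rows, columns=_BAND_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_band_table(path: str | Path):
    """Read a band table written by :func:`write_band_table`."""
    from .wavelet_sync import BandStats, BandSummary

    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    summaries = []
    for (pair, level, mclass), grp in df.groupby(
        ["pair", "level", "modality_class"], sort=False, dropna=False
    ):
        bands = [
            BandStats(
                lo=row.band_lo_s,
                hi=row.band_hi_s,
                mean_coherence=row.mean_coherence,
                circ_mean_phase_deg=row.circ_mean_phase_deg,
                resultant_length=row.resultant_length,
                n_valid_bins=int(row.n_valid_bins),
            )
            for row in grp.itertuples(index=False)
        ]
        summaries.append(
            BandSummary(
                pair=str(pair),
                level=str(level),
                modality_class=str(mclass),
                bands=bands,
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# plain-text series files (CLI currency)
# ---------------------------------------------------------------------------

def write_series(s: UniformSeries, path: str | Path) -> None:
    """Write a series as TSV with rate/start/label in ``#`` header lines."""
    with open(path, "w") as fh:
        fh.write(f"# rate_hz: {s.rate!r}\n")
        fh.write(f"# start_s: {s.start!r}\n")
        fh.write(f"# label: {s.label}\n")
        fh.write("value\n")
        for v in s.values:
            fh.write(f"{float(v)!r}\n")


def read_series(path: str | Path) -> UniformSeries:
    """Read a series written by :func:`write_series`."""
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line != "value":
                values.append(float(line))
    try:
        rate = float(meta["rate_hz"])
    except KeyError:
        raise ParseError(f"{path}: missing '# rate_hz:' header") from None
    start = float(meta.get("start_s", 0.0))
    if not math.isfinite(rate):
        raise ParseError(f"{path}: non-finite rate")
    return UniformSeries(
        np.asarray(values), rate=rate, start=start, label=meta.get("label", "")
    )
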