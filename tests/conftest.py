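"""Shared fixtures: small BVH/WAV/tier files built on the fly."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.io import wavfile


TWO_JOINT_BVH = """\
HIERARCHY
ROOT Hips
{
    OFFSET 0.0 0.0 0.0
    CHANNELS 6 Xposition Yposition Zposition Zrotation Xrotation Yrotation
    JOINT Head
    {
        OFFSET 0.0 10.0 0.0
        CHANNELS 3 Zrotation Xrotation Yrotation
        End Site
        {
            OFFSET 0.0 2.0 0.0
        }
    }
}
MOTION
Frames: 3
Frame Time: 0.0111111
0 0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0 0
"""


@pytest.fixture
def two_joint_bvh(tmp_path):
    p = tmp_path / "two_joint.bvh"
    p.write_text(TWO_JOINT_BVH)
    return p


def make_bvh(
    tmp_path,
    *,
    frames: np.ndarray,
    frame_time: float = 0.0111111,
    name: str = "fixture.bvh",
    hierarchy: str | None = None,
    declared_frames: int | None = None,
):
    """Write a BVH file with the two-joint hierarchy and given frame rows."""
    frames = np.atleast_2d(frames)
    header = hierarchy or TWO_JOINT_BVH.split("MOTION")[0]
    n = declared_frames if declared_frames is not None else frames.shape[0]
    rows = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in frames)
    text = (
        f"{header}MOTION\nFrames: {n}\nFrame Time: {frame_time}\n{rows}\n"
    )
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.fixture
def make_wav(tmp_path):
    def _make(data: np.ndarray, rate: int = 44100, name: str = "a.wav"):
        p = tmp_path / name
        wavfile.write(p, rate, data)
        return p

    return _make


@pytest.fixture
def make_tier_file(tmp_path):
    def _make(rows, name: str = "tiers.tsv"):
        p = tmp_path / name
        lines = ["speaker\tstart\tend"]
        lines += [f"{s}\t{a}\t{b}" for s, a, b in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
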