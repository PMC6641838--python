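"""Shared fixtures and builders for the mbplast test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mbplast.behavior import Epoch, EpochSchedule, Trajectory


def piecewise_constant(levels, seg_dur: float, eps: float = 1e-4, fly_id: str = "toy"):
    """Trajectory holding each level for seg_dur seconds with near-instant jumps."""
    t, x = [0.0], [float(levels[0])]
    tcur = 0.0
    for i, lv in enumerate(levels):
        tcur += seg_dur
        t.append(tcur - eps)
        x.append(float(lv))
        if i + 1 < len(levels):
            t.append(tcur)
            x.append(float(levels[i + 1]))
    return Trajectory(fly_id, np.array(t), np.array(x))


def single_epoch_schedule(duration: float, left: str, right: str, role: str) -> EpochSchedule:
    return EpochSchedule(epochs=(Epoch(0.0, duration, left=left, right=right, role=role),))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
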