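"""Single-fly conditioning scores from 1-D chamber trajectories.

A fly walks along a 50 mm chamber whose two halves carry independent
air/odor streams.  Scores are defined on side occupancy:

* ``preference`` — percentage of epoch time spent on one side of the
  chamber midline (time-weighted, not sample-counted).
* ``naive_avoidance_index`` — preference for the left side when it
  carries air minus preference for the left side when it carries odor.
* ``learning_index`` — preference for the trained-odor side before
  training minus after training, in percentage points.

Flies that enter the central choice zone fewer than a minimum number of
times during odor presentation are excluded from group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AIR = "air"

__all__ = [
    "AIR",
    "Trajectory",
    "Epoch",
    "Shock",
    "EpochSchedule",
    "BehaviorScore",
    "ScheduleError",
    "CoverageError",
    "preference",
    "naive_avoidance_index",
    "learning_index",
    "choice_zone_entries",
    "apply_exclusion",
    "score_fly",
]


class ScheduleError(ValueError):
    """Raised when an epoch schedule is inconsistent or an epoch is missing."""


class CoverageError(ValueError):
    """Raised when an epoch does not overlap the trajectory's time span."""


@dataclass(frozen=True)
class Epoch:
    """One stimulus epoch: half-open interval [t_start, t_end) in seconds."""

    t_start: float
    t_end: float
    left: str = AIR
    right: str = AIR
    role: str = "pretest"  # pretest | training | posttest | avoidance

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ScheduleError(f"epoch end {self.t_end} must exceed start {self.t_start}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def side_of(self, stimulus: str) -> str:
        """Which side ('left'/'right') carries *stimulus*; ScheduleError if absent."""
        if self.left == stimulus:
            return "left"
        if self.right == stimulus:
            return "right"
        raise ScheduleError(f"stimulus {stimulus!r} not present in epoch {self}")


@dataclass(frozen=True)
class Shock:
    """One electric-shock pulse (onset s, duration s, voltage V)."""

    t: float
    duration: float = 1.25
    voltage: float = 50.0


@dataclass(frozen=True)
class EpochSchedule:
    """Ordered, non-overlapping stimulus epochs plus shock pulses.

    Shock pulses must fall inside a training epoch.
    """

    epochs: tuple[Epoch, ...]
    shocks: tuple[Shock, ...] = ()

    def __post_init__(self) -> None:
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        object.__setattr__(self, "shocks", tuple(self.shocks))
        for a, b in zip(epochs, epochs[1:]):
            if b.t_start < a.t_end:
                raise ScheduleError(f"epochs overlap or are unordered: {a} then {b}")
        training = [e for e in epochs if e.role == "training"]
        for s in self.shocks:
            if not any(e.t_start <= s.t and s.t + s.duration <= e.t_end for e in training):
                raise ScheduleError(f"shock at {s.t}s falls outside all training epochs")

    def by_role(self, role: str) -> Epoch:
        matches = [e for e in self.epochs if e.role == role]
        if not matches:
            raise ScheduleError(f"no epoch with role {role!r}")
        return matches[0]

    def odor_epochs(self) -> tuple[Epoch, ...]:
        """Epochs during which at least one side carries an odor."""
        return tuple(e for e in self.epochs if e.left != AIR or e.right != AIR)

    def shifted(self, dt: float) -> "EpochSchedule":
        return EpochSchedule(
            epochs=tuple(
                replace(e, t_start=e.t_start + dt, t_end=e.t_end + dt) for e in self.epochs
            ),
            shocks=tuple(replace(s, t=s.t + dt) for s in self.shocks),
        )


@dataclass
class Trajectory:
    """Time-stamped 1-D fly positions within one chamber.

    ``x`` is measured in mm from the left wall (x = 0); the chamber
    midline sits at ``chamber_length / 2``.
    """

    fly_id: str
    t: np.ndarray
    x: np.ndarray
    chamber_length: float = 50.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.x < 0) or np.any(self.x > self.chamber_length):
            raise ValueError("positions exceed chamber bounds")

    @property
    def midline(self) -> float:
        return self.chamber_length / 2.0

    def shifted(self, dt: float) -> "Trajectory":
        return Trajectory(self.fly_id, self.t + dt, self.x.copy(), self.chamber_length)


@dataclass
class BehaviorScore:
    """Per-fly conditioning scores with the exclusion bookkeeping."""

    fly_id: str
    preference_pre: float = np.nan
    preference_post: float = np.nan
    learning_index: float = np.nan
    avoidance_index: float = np.nan
    n_choice_entries: int = 0
    excluded: bool = False
    group: str = ""


def _interval_weights(traj: Trajectory, epoch: Epoch) -> tuple[np.ndarray, np.ndarray]:
    """Overlap durations and midpoint positions of inter-sample intervals.

    Each interval [t_i, t_{i+1}] is clipped to the epoch; the side is
    assigned by the position interpolated at the clipped interval's time
    midpoint (trapezoidal occupancy, robust to uneven sampling).
    """
    t0, t1 = traj.t[:-1], traj.t[1:]
    lo = np.maximum(t0, epoch.t_start)
    hi = np.minimum(t1, epoch.t_end)
    w = np.clip(hi - lo, 0.0, None)
    sel = w > 0
    if not np.any(sel):
        raise CoverageError(
            f"epoch [{epoch.t_start}, {epoch.t_end}) does not overlap trajectory "
            f"span [{traj.t[0]}, {traj.t[-1]}]"
        )
    tm = 0.5 * (lo[sel] + hi[sel])
    frac = (tm - t0[sel]) / (t1[sel] - t0[sel])
    xm = traj.x[:-1][sel] + frac * (traj.x[1:][sel] - traj.x[:-1][sel])
    return w[sel], xm


def preference(traj: Trajectory, epoch: Epoch, side: str = "left") -> float:
    """Percentage of epoch time spent on one side of the chamber midline.

    Time exactly at the midline counts toward neither side and is
    excluded from the denominator.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    w, xm = _interval_weights(traj, epoch)
    mid = traj.midline
    t_left = w[xm < mid].sum()
    t_right = w[xm > mid].sum()
    denom = t_left + t_right
    if denom <= 0:
        # fly pinned to the midline for the whole epoch
        return np.nan
    frac = t_left / denom if side == "left" else t_right / denom
    return 100.0 * frac


def naive_avoidance_index(
    traj: Trajectory, epoch_air_left: Epoch, epoch_odor_left: Epoch
) -> float:
    """(preference for left when it carries air) − (preference for left when it carries odor).

    Positive values mean the fly avoids the odor.
    """
    if epoch_air_left.left != AIR:
        raise ScheduleError("epoch_air_left must carry air on the left")
    if epoch_odor_left.left == AIR:
        raise ScheduleError("epoch_odor_left must carry an odor on the left")
    return preference(traj, epoch_air_left, "left") - preference(traj, epoch_odor_left, "left")


def learning_index(
    traj_pre: Trajectory,
    epoch_pre: Epoch,
    traj_post: Trajectory,
    epoch_post: Epoch,
    trained_odor: str,
) -> float:
    """Preference for the trained-odor side before training minus after.

    The side carrying the trained odor is looked up in each epoch, so
    side swaps between pretest and posttest are handled. Positive values
    mean learned avoidance.
    """
    side_pre = epoch_pre.side_of(trained_odor)
    side_post = epoch_post.side_of(trained_odor)
    return preference(traj_pre, epoch_pre, side_pre) - preference(traj_post, epoch_post, side_post)


def choice_zone_entries(
    traj: Trajectory,
    odor_epochs: tuple[Epoch, ...],
    zone_halfwidth: float = 2.5,
) -> int:
    """Count outside→inside transitions of the central choice zone.

    The zone is [midline − h, midline + h]; transitions are counted only
    while an odor-presentation epoch is active (all odor epochs jointly).
    A fly starting inside the zone scores no entry until it first exits.
    """
    if not 0 < zone_halfwidth < traj.chamber_length / 2:
        raise ValueError("zone_halfwidth must lie in (0, chamber_length/2)")
    inside = np.abs(traj.x - traj.midline) <= zone_halfwidth
    in_epoch = np.zeros(traj.t.shape, dtype=bool)
    for e in odor_epochs:
        in_epoch |= (traj.t >= e.t_start) & (traj.t < e.t_end)
    enter = inside[1:] & ~inside[:-1] & in_epoch[1:]
    return int(enter.sum())


def apply_exclusion(
    scores: list[BehaviorScore], min_entries: int = 4
) -> tuple[list[BehaviorScore], list[BehaviorScore]]:
    """Split scores into (kept, excluded) by the choice-zone entry rule.

    Flies with fewer than ``min_entries`` entries during odor
    presentation are flagged ``excluded`` and removed from group
    statistics; the exclusion log is returned alongside.
    """
    kept: list[BehaviorScore] = []
    excluded: list[BehaviorScore] = []
    for s in scores:
        if s.n_choice_entries < min_entries:
            s.excluded = True
            excluded.append(s)
        else:
            s.excluded = False
            kept.append(s)
    return kept, excluded


def score_fly(
    traj_pre: Trajectory,
    schedule_pre: EpochSchedule,
    traj_post: Trajectory,
    schedule_post: EpochSchedule,
    trained_odor: str,
    zone_halfwidth: float = 2.5,
    group: str = "",
) -> BehaviorScore:
    """Full per-fly score: preferences, learning index, choice-zone entries.

    Entries are counted jointly over the odor epochs of both sessions.
    """
    epoch_pre = schedule_pre.by_role("pretest")
    epoch_post = schedule_post.by_role("posttest")
    side_pre = epoch_pre.side_of(trained_odor)
    side_post = epoch_post.side_of(trained_odor)
    p_pre = preference(traj_pre, epoch_pre, side_pre)
    p_post = preference(traj_post, epoch_post, side_post)
    entries = choice_zone_entries(
        traj_pre, schedule_pre.odor_epochs(), zone_halfwidth
    ) + choice_zone_entries(traj_post, schedule_post.odor_epochs(), zone_halfwidth)
    return BehaviorScore(
        fly_id=traj_pre.fly_id,
        preference_pre=p_pre,
        preference_post=p_post,
        learning_index=p_pre - p_post,
        n_choice_entries=entries,
        group=group,
    )
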