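"""Ground-truth synthetic data: fly trajectories, GCaMP-like movies,
MBON response tables and qPCR Ct tables.

Every generator takes an explicit seed, draws all randomness from one
``numpy.random.Generator`` per call, and returns the ground truth needed
by downstream recovery tests alongside the data.

Walk model
----------
The fly is a two-state (left-going / right-going) walker discretized at
``dt``: direction switches occur at rate ``step_rate`` and walls reflect.
On epochs where one chamber side carries odor and the other air, every
midline crossing attempt independently sends the fly to the air side
with probability ``bias_air / (1 + bias_air)``.  Because within-side
dynamics are mirror-symmetric, excursion durations on the two sides are
identically distributed, so the stationary air-side occupancy is exactly

    P(air) = bias_air / (1 + bias_air)

— the closed form used by the analytic recovery tests (bias 1 → 50%,
bias 3 → 75%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import AIR, Epoch, EpochSchedule, Shock, Trajectory
from .imaging import MovieStack

__all__ = [
    "WalkParams",
    "MovieParams",
    "MbonSimParams",
    "MovieTruth",
    "ConditioningExperiment",
    "air_side_occupancy",
    "expected_learning_index",
    "simulate_trajectory",
    "conditioning_protocol",
    "simulate_conditioning_experiment",
    "response_kinetics",
    "simulate_movie",
    "simulate_mbon_table",
    "simulate_ct_table",
    "random_baseline_image",
    "random_response_map",
]


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkParams:
    """Biased-telegraph-walk parameters for a single fly.

    ``bias_air`` weights motion toward the air side on odor-vs-air
    epochs; 1 is a symmetric walk, values > 1 mean odor avoidance.
    """

    step_rate: float = 0.5  # direction-switch rate, 1/s
    speed: float = 10.0  # mm/s
    bias_air: float = 1.0
    chamber_length: float = 50.0
    dt: float = 0.1  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chamber_length <= 0:
            raise ValueError("chamber_length must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.bias_air < 0:
            raise ValueError("bias_air must be nonnegative")
        if self.speed < 0 or self.step_rate < 0:
            raise ValueError("speed and step_rate must be nonnegative")
        if self.speed * self.dt >= self.chamber_length / 2:
            raise ValueError("step length must be below half the chamber length")


def air_side_occupancy(bias_air: float) -> float:
    """Closed-form stationary air-side occupancy of the biased walk, as a fraction."""
    return bias_air / (1.0 + bias_air)


def expected_learning_index(pre_bias: float, post_bias: float) -> float:
    """Closed-form expected learning index (percentage points).

    The trained-odor side occupancy is ``1/(1+bias)``, so the expected
    index is ``100·[1/(1+pre_bias) − 1/(1+post_bias)]``.
    """
    return 100.0 * (1.0 / (1.0 + pre_bias) - 1.0 / (1.0 + post_bias))


def _epoch_bias_sides(schedule: EpochSchedule) -> list[tuple[Epoch, str | None]]:
    """For each epoch, which side ('left'/'right') carries air in an
    odor-vs-air configuration; None when the epoch is symmetric."""
    out = []
    for e in schedule.epochs:
        if e.left == AIR and e.right != AIR:
            out.append((e, "left"))
        elif e.right == AIR and e.left != AIR:
            out.append((e, "right"))
        else:
            out.append((e, None))
    return out


def simulate_trajectory(
    params: WalkParams,
    schedule: EpochSchedule,
    fly_id: str = "fly0",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one fly over the full span of a stimulus schedule.

    Samples are taken at ``t0 + i·dt`` for ``i = 0 .. round(span/dt)−1``.
    Identical seeds reproduce identical trajectories bit-for-bit.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    epochs = _epoch_bias_sides(schedule)
    t0 = schedule.epochs[0].t_start
    t_end = schedule.epochs[-1].t_end
    n = int(round((t_end - t0) / params.dt))
    L, m = params.chamber_length, params.chamber_length / 2.0
    step = params.speed * params.dt
    p_switch = 1.0 - math.exp(-params.step_rate * params.dt)
    p_air = air_side_occupancy(params.bias_air)

    t = t0 + params.dt * np.arange(n)
    x = np.empty(n)
    # stationary initialization: side drawn from the closed-form occupancy of
    # the first epoch, position uniform within the side.  With this start the
    # expected air-side occupancy equals bias/(1+bias) for ANY epoch length,
    # not just asymptotically (renewal argument: every midline crossing and
    # the initial segment choose the side i.i.d. with the same probability).
    init_air_side = epochs[0][1]
    if init_air_side is None:
        pos = rng.uniform(0.0, L)
    else:
        on_air = rng.random() < p_air
        left_half = (init_air_side == "left") == on_air
        pos = rng.uniform(0.0, m) if left_half else rng.uniform(m, L)
    d = 1.0 if rng.random() < 0.5 else -1.0
    x[0] = pos
    # epoch lookup per sample (air side active during that sample's step)
    ei = 0
    for i in range(1, n):
        ti = t[i - 1]
        while ei < len(epochs) - 1 and ti >= epochs[ei][0].t_end:
            ei += 1
        air_side = epochs[ei][1] if epochs[ei][0].t_start <= ti < epochs[ei][0].t_end else None
        if rng.random() < p_switch:
            d = -d
        new = pos + d * step
        if new < 0:
            new, d = -new, -d
        elif new > L:
            new, d = 2 * L - new, -d
        if air_side is not None and (pos < m) != (new < m):
            p_left = p_air if air_side == "left" else 1.0 - p_air
            go_left = rng.random() < p_left
            if go_left != (new < m):
                new, d = 2 * m - new, -d
        pos = new
        x[i] = pos
    return Trajectory(fly_id=fly_id, t=t, x=x, chamber_length=L)


def conditioning_protocol(
    trained_odor: str = "MCH",
    other_stim: str = AIR,
    pretest_s: float = 120.0,
    training_s: float = 60.0,
    posttest_s: float = 120.0,
    n_shocks: int = 12,
    shock_duration: float = 1.25,
    shock_voltage: float = 50.0,
) -> tuple[EpochSchedule, EpochSchedule, EpochSchedule]:
    """Pretest / training / posttest schedules for one conditioning session.

    The trained odor sits on the left during pretest and on the right
    during posttest (side swap); training pairs the trained odor with
    ``n_shocks`` equally spaced shock pulses.  Each phase runs on its own
    clock starting at 0 s.
    """
    pre = EpochSchedule(
        epochs=(Epoch(0.0, pretest_s, left=trained_odor, right=other_stim, role="pretest"),)
    )
    gap = training_s / n_shocks
    shocks = tuple(
        Shock(t=i * gap, duration=shock_duration, voltage=shock_voltage) for i in range(n_shocks)
    )
    train = EpochSchedule(
        epochs=(Epoch(0.0, training_s, left=trained_odor, right=trained_odor, role="training"),),
        shocks=shocks,
    )
    post = EpochSchedule(
        epochs=(Epoch(0.0, posttest_s, left=other_stim, right=trained_odor, role="posttest"),)
    )
    return pre, train, post


@dataclass
class ConditioningExperiment:
    """Simulated single-fly conditioning cohort with its ground truth."""

    flies: list[dict]  # fly_id, group, traj_pre, traj_post
    schedule_pre: EpochSchedule
    schedule_post: EpochSchedule
    trained_odor: str
    expected_li_trained: float
    expected_li_control: float


def simulate_conditioning_experiment(
    pre_bias: float,
    post_bias_trained: float,
    post_bias_control: float,
    n_flies: int,
    seed: int = 0,
    walk: WalkParams | None = None,
    trained_odor: str = "MCH",
    test_s: float = 180.0,
) -> ConditioningExperiment:
    """Trained and control cohorts of (pretest, posttest) trajectories.

    Expected learning indices follow the walk's closed form; the control
    group's expectation is 0 when ``post_bias_control == pre_bias``.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    base = walk or WalkParams()
    rng = np.random.default_rng(seed)
    pre_sched, _, post_sched = conditioning_protocol(
        trained_odor=trained_odor, pretest_s=test_s, posttest_s=test_s
    )
    flies = []
    for group, post_bias in (("trained", post_bias_trained), ("control", post_bias_control)):
        for i in range(n_flies):
            fly_id = f"{group}_{i:03d}"
            wp_pre = WalkParams(
                base.step_rate, base.speed, pre_bias, base.chamber_length, base.dt, base.seed
            )
            wp_post = WalkParams(
                base.step_rate, base.speed, post_bias, base.chamber_length, base.dt, base.seed
            )
            traj_pre = simulate_trajectory(wp_pre, pre_sched, fly_id=fly_id, rng=rng)
            traj_post = simulate_trajectory(wp_post, post_sched, fly_id=fly_id, rng=rng)
            flies.append(
                dict(fly_id=fly_id, group=group, traj_pre=traj_pre, traj_post=traj_post)
            )
    return ConditioningExperiment(
        flies=flies,
        schedule_pre=pre_sched,
        schedule_post=post_sched,
        trained_odor=trained_odor,
        expected_li_trained=expected_learning_index(pre_bias, post_bias_trained),
        expected_li_control=expected_learning_index(pre_bias, post_bias_control),
    )


# --------------------------------------------------------------------------
# imaging
# --------------------------------------------------------------------------

def response_kinetics(
    t: np.ndarray, window: tuple[float, float], tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Peak-normalized double-exponential response confined to a window.

    k(s) = (e^{−s/τ_d} − e^{−s/τ_r}) / k_max for s = t − t_start inside
    [t_start, t_end), 0 outside; k_max is the analytic maximum of the
    unnormalized kernel, attained at s* = ln(τ_d/τ_r)·τ_r τ_d/(τ_d−τ_r),
    so an amplitude ``a`` means an asymptotic peak dF/F of ``a``.
    """
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    s = t - window[0]
    inside = (t >= window[0]) & (t < window[1])
    raw = np.where(inside, np.exp(-s / tau_decay) - np.exp(-s / tau_rise), 0.0)
    s_star = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    k_max = math.exp(-s_star / tau_decay) - math.exp(-s_star / tau_rise)
    return raw / k_max


@dataclass
class MovieParams:
    """Everything needed to synthesize one GCaMP-like movie.

    ``shape`` is (T, Y, X) or (T, Z, Y, X); ``response_maps`` holds one
    nonnegative peak-dF/F field per odor matching the spatial shape.
    ``knockdown_gain`` multiplies response amplitudes on the pixels of
    ``knockdown_mask`` (the designated "knockdown" subset).
    """

    shape: tuple[int, ...]
    frame_period: float
    baseline_image: np.ndarray
    response_maps: dict[str, np.ndarray]
    stim_windows: dict[str, tuple[float, float]]
    tau_rise: float = 0.2
    tau_decay: float = 2.0
    noise_sd: float = 0.0
    xy_shifts: np.ndarray | None = None  # (T, 2) ints
    z_shifts: np.ndarray | None = None  # (T,) ints
    corrupt_frames: tuple[int, ...] = ()
    knockdown_gain: float = 1.0
    knockdown_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (3, 4):
            raise ValueError("shape must be (T, Y, X) or (T, Z, Y, X)")
        if self.knockdown_gain < 0:
            raise ValueError("knockdown_gain must be nonnegative")
        spatial = tuple(self.shape[1:])
        self.baseline_image = np.asarray(self.baseline_image, dtype=float)
        if self.baseline_image.shape != spatial:
            raise ValueError("baseline_image shape must match the spatial shape")
        if np.any(self.baseline_image < 0):
            raise ValueError("baseline_image must be nonnegative")
        for name, m in self.response_maps.items():
            m = np.asarray(m, dtype=float)
            if m.shape != spatial:
                raise ValueError(f"response map {name!r} shape mismatch")
            if np.any(m < 0):
                raise ValueError(f"response map {name!r} has negative amplitudes")
            self.response_maps[name] = m
        dur = self.shape[0] * self.frame_period
        for name, (a, b) in self.stim_windows.items():
            if name not in self.response_maps:
                raise ValueError(f"stimulus window {name!r} lacks a response map")
            if not (0 <= a < b <= dur):
                raise ValueError(f"stimulus window {name!r} outside movie duration")


@dataclass
class MovieTruth:
    """Generator-side ground truth for downstream recovery tests."""

    xy_shifts: np.ndarray  # (T, 2) applied (dy, dx)
    z_shifts: np.ndarray  # (T,)
    corrupt_frames: tuple[int, ...]
    effective_maps: dict[str, np.ndarray]  # response maps after knockdown gain
    responsive_sets: dict[str, np.ndarray]  # bool, per odor
    stim_mean_k: dict[str, float]  # mean kinetics over in-window frames
    peak_k: dict[str, float]  # max kinetics over in-window frames
    clean_frames: np.ndarray  # bool, True where frame was not corrupted


def simulate_movie(params: MovieParams) -> tuple[MovieStack, MovieTruth]:
    """Synthesize a movie F(t) = shifted(baseline·(1 + Σ map·k(t))) + noise.

    Corrupt frames are replaced by a spatial permutation of the baseline
    (decorrelated content emulating a large axial jump); noise is
    additive Gaussian clipped at zero; all randomness flows from the
    params seed.
    """
    rng = np.random.default_rng(params.seed)
    T = params.shape[0]
    volumetric = len(params.shape) == 4
    times = np.arange(T) * params.frame_period

    eff = {}
    gain_field = np.ones(params.baseline_image.shape)
    if params.knockdown_mask is not None:
        gain_field = np.where(np.asarray(params.knockdown_mask, bool), params.knockdown_gain, 1.0)
    for name, m in params.response_maps.items():
        eff[name] = m * gain_field

    modulation = np.ones((T,) + params.baseline_image.shape)
    stim_mean_k, peak_k = {}, {}
    for name, window in params.stim_windows.items():
        k = response_kinetics(times, window, params.tau_rise, params.tau_decay)
        modulation += k.reshape((T,) + (1,) * params.baseline_image.ndim) * eff[name]
        inside = (times >= window[0]) & (times < window[1])
        stim_mean_k[name] = float(k[inside].mean())
        peak_k[name] = float(k[inside].max())

    data = params.baseline_image[None] * modulation

    xy = np.zeros((T, 2), dtype=int)
    if params.xy_shifts is not None:
        xy = np.asarray(params.xy_shifts, dtype=int)
        if xy.shape != (T, 2):
            raise ValueError("xy_shifts must have shape (T, 2)")
    zs = np.zeros(T, dtype=int)
    if params.z_shifts is not None:
        zs = np.asarray(params.z_shifts, dtype=int)
        if zs.shape != (T,):
            raise ValueError("z_shifts must have shape (T,)")
        if not volumetric and np.any(zs != 0):
            raise ValueError("z_shifts require a volumetric shape")

    for t in range(T):
        frame = data[t]
        if volumetric and zs[t] != 0:
            z = frame.shape[0]
            idx = np.clip(np.arange(z) - zs[t], 0, z - 1)
            frame = frame[idx]
        if xy[t, 0] or xy[t, 1]:
            frame = np.roll(frame, (xy[t, 0], xy[t, 1]), axis=(-2, -1))
        data[t] = frame

    clean = np.ones(T, dtype=bool)
    for f in params.corrupt_frames:
        perm = rng.permutation(params.baseline_image.size)
        data[f] = params.baseline_image.ravel()[perm].reshape(params.baseline_image.shape)
        clean[f] = False

    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    movie = MovieStack(
        data=data,
        frame_period=params.frame_period,
        stim_windows=dict(params.stim_windows),
        meta=dict(synthetic=True, seed=params.seed, volumetric=volumetric),
    )
    truth = MovieTruth(
        xy_shifts=xy,
        z_shifts=zs,
        corrupt_frames=tuple(params.corrupt_frames),
        effective_maps=eff,
        responsive_sets={
            n: (m > 0) & (params.baseline_image > 0) for n, m in eff.items()
        },
        stim_mean_k=stim_mean_k,
        peak_k=peak_k,
        clean_frames=clean,
    )
    return movie, truth


def random_baseline_image(
    spatial_shape: tuple[int, ...],
    rng: np.random.Generator,
    mean_level: float = 100.0,
    blob_sd: float = 6.0,
) -> np.ndarray:
    """Smooth, strictly positive random baseline (Gaussian-filtered noise blobs).

    Smoothing acts on the last two (Y, X) axes only, so the planes of a
    volumetric baseline stay mutually distinct.
    """
    from scipy import ndimage

    raw = rng.normal(0.0, 1.0, size=spatial_shape)
    sigma = (0,) * (len(spatial_shape) - 2) + (blob_sd, blob_sd)
    smooth = ndimage.gaussian_filter(raw, sigma=sigma, mode="wrap")
    smooth = (smooth - smooth.min()) / max(np.ptp(smooth), 1e-12)
    return mean_level * (0.25 + 0.75 * smooth)


def random_response_map(
    spatial_shape: tuple[int, ...],
    rng: np.random.Generator,
    frac_active: float = 0.1,
    amplitude: float = 1.0,
    cv: float = 0.2,
    within: np.ndarray | None = None,
) -> np.ndarray:
    """Sparse nonnegative peak-dF/F field: a random pixel subset (optionally
    confined to ``within``) gets lognormal amplitudes with mean ``amplitude``."""
    m = np.zeros(spatial_shape)
    candidates = np.flatnonzero(within.ravel()) if within is not None else np.arange(m.size)
    n_active = max(1, int(round(frac_active * candidates.size)))
    chosen = rng.choice(candidates, size=n_active, replace=False)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    amps = amplitude * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n_active))
    m.ravel()[chosen] = amps
    return m


# --------------------------------------------------------------------------
# MBON responses and qPCR
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MbonSimParams:
    """Per-fly MBON peak-response generator (trained vs mock cohorts).

    ``depression`` multiplies the trained odor's amplitude in the trained
    group; ``cv`` is the per-measurement coefficient of variation, of
    which a fraction ``shared_frac`` of the log-variance is a per-fly
    gain shared across odors (GCaMP expression / optical access — the
    very variability within-fly ratios are designed to cancel).
    """

    n_per_group: int = 5
    base_amp: tuple[tuple[str, float], ...] = (("MCH", 1.0), ("OCT", 1.0), ("IAA", 1.0))
    depression: float = 0.5
    cv: float = 0.2
    shared_frac: float = 0.5
    trained_odor: str = "MCH"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.depression <= 1:
            raise ValueError("depression must lie in (0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if not 0 <= self.shared_frac <= 1:
            raise ValueError("shared_frac must lie in [0, 1]")


def simulate_mbon_table(params: MbonSimParams) -> pd.DataFrame:
    """Long-format per-fly MBON peak responses for trained and mock groups.

    Columns: fly_id, group ('trained'/'mock'), odor, peak_dff.  The
    trained group's expected trained:untrained ratio is ``depression``
    times the base ratio; with cv = 0 every fly hits it exactly.
    """
    rng = np.random.default_rng(params.seed)
    base = dict(params.base_amp)
    s2 = math.log(1.0 + params.cv**2)
    sg = math.sqrt(params.shared_frac * s2)
    so = math.sqrt((1.0 - params.shared_frac) * s2)
    rows = []
    for group in ("trained", "mock"):
        for i in range(params.n_per_group):
            fly = f"{group}_{i:03d}"
            g = rng.normal(-sg**2 / 2.0, sg) if sg > 0 else 0.0
            for odor, amp in base.items():
                e = rng.normal(-so**2 / 2.0, so) if so > 0 else 0.0
                dep = params.depression if (group == "trained" and odor == params.trained_odor) else 1.0
                rows.append(
                    dict(fly_id=fly, group=group, odor=odor, peak_dff=amp * dep * math.exp(g + e))
                )
    return pd.DataFrame(rows)


def simulate_ct_table(
    true_fold_changes: dict[str, float],
    ct_noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    calibrator: str = "control",
    reference_ct: float = 20.0,
    calibrator_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """qPCR Ct table whose noiseless values invert to the designed folds.

    Fold changes are relative to ``calibrator`` (implicitly fold 1); by
    construction ``fold = 2^(−ΔΔCt)`` holds exactly when
    ``ct_noise_sd = 0``.  Columns: sample, replicate, target_ct,
    reference_ct.
    """
    folds = dict(true_fold_changes)
    folds.setdefault(calibrator, 1.0)
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in folds.items():
        target_base = reference_ct + calibrator_delta_ct - math.log2(fold)
        for rep in range(n_replicates):
            rows.append(
                dict(
                    sample=sample,
                    replicate=rep,
                    target_ct=target_base + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0),
                    reference_ct=reference_ct + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0),
                )
            )
    return pd.DataFrame(rows)
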