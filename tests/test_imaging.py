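"""Unit tests for motion correction, frame QC, smoothing and dF/F maps."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import _oracles
from mbplast import synthetic
from mbplast.imaging import (
    MovieStack,
    _best_circular_shift,
    compute_activity_map,
    correct_motion_xy,
    correct_motion_z,
    peak_response,
    qc_discard_frames,
    roi_dff_trace,
    smooth_for_analysis,
)


def _random_movie(rng, T=12, spatial=(24, 24), **kwargs):
    baseline = synthetic.random_baseline_image(spatial, rng)
    params = synthetic.MovieParams(
        shape=(T,) + spatial,
        frame_period=0.2,
        baseline_image=baseline,
        response_maps={},
        stim_windows={},
        seed=int(rng.integers(2**31)),
        **kwargs,
    )
    return synthetic.simulate_movie(params)


# --------------------------------------------------------------------------
# XY motion
# --------------------------------------------------------------------------

def test_best_shift_matches_bruteforce_pearson(rng):
    for _ in range(10):
        ref = rng.normal(size=(16, 16))
        frame = rng.normal(size=(16, 16))
        assert _best_circular_shift(ref, frame, 3) == _oracles.best_shift_bruteforce(ref, frame, 3)


def test_best_shift_recovers_known_roll(rng):
    ref = rng.normal(size=(20, 20))
    for dy, dx in [(0, 0), (2, -3), (-4, 1)]:
        frame = np.roll(ref, (-dy, -dx), axis=(0, 1))  # needs roll by (dy, dx) to match
        assert _best_circular_shift(ref, frame, 5) == (dy, dx)


def test_xy_correction_zero_for_still_movie(rng):
    movie, _ = _random_movie(rng)
    res = correct_motion_xy(movie, max_shift=5)
    assert np.array_equal(res.shifts, np.zeros((movie.n_frames, 2), dtype=int))
    assert np.array_equal(res.movie.data, movie.data)


def test_xy_correction_inverts_injected_shifts(rng):
    T = 12
    xy = np.zeros((T, 2), dtype=int)
    xy[6:] = (3, -2)
    movie, truth = _random_movie(rng, T=T, xy_shifts=xy)
    res = correct_motion_xy(movie, reference="first", max_shift=5)
    assert np.array_equal(res.shifts, -truth.xy_shifts)
    # compose-to-identity: corrected movie equals the unshifted movie
    still = np.broadcast_to(movie.data[0], movie.data.shape)
    assert np.allclose(res.movie.data, still)


def test_xy_correction_clamps_at_search_boundary(rng):
    T = 8
    xy = np.zeros((T, 2), dtype=int)
    xy[4:] = (5, 0)
    movie, _ = _random_movie(rng, T=T, xy_shifts=xy)
    res = correct_motion_xy(movie, reference="first", max_shift=3)
    assert res.clamped[4:].all()
    assert np.all(np.abs(res.shifts) <= 3)


def test_xy_correction_constant_frames_flagged():
    data = np.ones((5, 24, 24))
    movie = MovieStack(data, frame_period=0.2)
    with pytest.warns(UserWarning, match="constant"):
        res = correct_motion_xy(movie, max_shift=5)
    assert res.constant_frames.all()
    assert np.array_equal(res.shifts, np.zeros((5, 2), dtype=int))


def test_xy_correction_max_shift_validation(rng):
    movie, _ = _random_movie(rng, spatial=(20, 20))
    with pytest.raises(ValueError):
        correct_motion_xy(movie, max_shift=5)  # not < 20/4


# --------------------------------------------------------------------------
# Z motion
# --------------------------------------------------------------------------

def test_z_correction_zero_for_still_volume(rng):
    movie, _ = _random_movie(rng, T=10, spatial=(4, 16, 16))
    res = correct_motion_z(movie)
    assert np.array_equal(res.offsets, np.zeros(10, dtype=int))
    assert np.array_equal(res.movie.data, movie.data)


def test_z_correction_inverts_minority_drift(rng):
    T = 20
    zs = np.zeros(T, dtype=int)
    zs[15:] = 1  # late drift on a minority of frames
    movie, truth = _random_movie(rng, T=T, spatial=(4, 16, 16), z_shifts=zs)
    res = correct_motion_z(movie)
    assert np.array_equal(res.offsets, -truth.z_shifts)
    assert res.padded[15:].all() and not res.padded[:15].any()


def test_z_correction_single_plane_warns(rng):
    movie, _ = _random_movie(rng, T=5, spatial=(1, 16, 16))
    with pytest.warns(UserWarning, match="fewer than 2 planes"):
        res = correct_motion_z(movie)
    assert np.array_equal(res.movie.data, movie.data)


def test_z_correction_tie_resolves_to_zero():
    # all planes identical: every offset correlates equally; pick 0
    plane = np.random.default_rng(0).normal(size=(16, 16)) ** 2
    data = np.broadcast_to(plane, (6, 4, 16, 16)).copy()
    movie = MovieStack(data, frame_period=0.2)
    res = correct_motion_z(movie)
    assert np.array_equal(res.offsets, np.zeros(6, dtype=int))


# --------------------------------------------------------------------------
# frame QC
# --------------------------------------------------------------------------

def test_qc_keeps_clean_noise_movie(rng):
    movie, _ = _random_movie(rng, T=60, noise_sd=2.0)
    res = qc_discard_frames(movie, movie.data.mean(axis=0), threshold="auto")
    assert res.kept.all()
    assert not res.excessive_discard


def test_qc_discards_corrupt_frames_auto(rng):
    movie, truth = _random_movie(rng, T=60, noise_sd=2.0, corrupt_frames=(10, 30, 45))
    baseline = movie.data[truth.clean_frames].mean(axis=0)
    res = qc_discard_frames(movie, baseline, threshold="auto")
    assert not res.kept[[10, 30, 45]].any()
    assert res.kept[truth.clean_frames].all()


def test_qc_explicit_threshold_and_validation(rng):
    movie, _ = _random_movie(rng, T=20, noise_sd=2.0)
    res = qc_discard_frames(movie, movie.data.mean(axis=0), threshold=-1.0)
    assert res.kept.all()
    with pytest.raises(ValueError):
        qc_discard_frames(movie, movie.data.mean(axis=0), threshold=2.0)
    with pytest.raises(ValueError):
        qc_discard_frames(movie, np.ones(movie.data.shape[1:]))  # constant baseline


def test_qc_excessive_discard_flag(rng):
    movie, truth = _random_movie(rng, T=10, noise_sd=0.5, corrupt_frames=tuple(range(6)))
    baseline = movie.data[truth.clean_frames].mean(axis=0)
    with pytest.warns(UserWarning, match="QC discarded"):
        res = qc_discard_frames(movie, baseline, threshold=0.9)
    assert res.excessive_discard


def test_qc_deterministic_over_seeds():
    # the auto rule never discards clean frames of shift-free noise movies
    for seed in range(10):
        rng = np.random.default_rng(seed)
        movie, _ = _random_movie(rng, T=50, noise_sd=3.0)
        res = qc_discard_frames(movie, movie.data.mean(axis=0), threshold="auto")
        assert res.kept.all()


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def test_smoothing_preserves_constant(rng):
    movie = MovieStack(np.full((4, 20, 20), 7.0), frame_period=0.2)
    out = smooth_for_analysis(movie)
    assert np.allclose(out.data, 7.0)


def test_smoothing_matches_dense_convolution(rng):
    img = rng.uniform(1, 10, size=(18, 18))
    movie = MovieStack(img[None], frame_period=0.2)
    out = smooth_for_analysis(movie, sigma=2.0, radius=2)
    oracle = _oracles.smooth_dense(img, sigma=2.0, radius=2)
    assert np.max(np.abs(out.data[0] - oracle)) < 1e-9


def test_smoothing_kernel_footprint(rng):
    # a delta spreads over exactly a 5x5 block and keeps unit mass
    img = np.zeros((21, 21))
    img[10, 10] = 1.0
    movie = MovieStack(img[None], frame_period=0.2)
    out = smooth_for_analysis(movie).data[0]
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(out[:8, :] == 0) and np.all(out[13:, :] == 0)
    assert np.all(out[:, :8] == 0) and np.all(out[:, 13:] == 0)
    assert out[10, 10] == out.max()


def test_smoothing_volumetric_acts_per_plane(rng):
    vol = rng.uniform(1, 5, size=(2, 3, 16, 16))
    movie = MovieStack(vol, frame_period=0.2)
    out = smooth_for_analysis(movie)
    for t in range(2):
        for z in range(3):
            single = smooth_for_analysis(MovieStack(vol[t, z][None], frame_period=0.2)).data[0]
            assert np.allclose(out.data[t, z], single)


# --------------------------------------------------------------------------
# activity maps and ROI traces
# --------------------------------------------------------------------------

def _response_movie(rng, amplitude=0.8):
    spatial = (20, 20)
    baseline = synthetic.random_baseline_image(spatial, rng)
    m = np.zeros(spatial)
    m[5:9, 5:9] = amplitude
    params = synthetic.MovieParams(
        shape=(40,) + spatial,
        frame_period=0.2,
        baseline_image=baseline,
        response_maps={"MCH": m},
        stim_windows={"MCH": (4.0, 6.0)},
        seed=0,
    )
    return synthetic.simulate_movie(params), m


def test_activity_map_noiseless_exact(rng):
    (movie, truth), m = _response_movie(rng)
    amap = compute_activity_map(movie, (0.0, 4.0), (4.0, 6.0))
    expected = m * truth.stim_mean_k["MCH"]
    assert np.nanmax(np.abs(amap.dff - expected)) < 1e-12
    assert np.array_equal(amap.responsive, truth.responsive_sets["MCH"])
    assert amap.valid.all()


def test_activity_map_scale_invariant(rng):
    (movie, _), _ = _response_movie(rng)
    amap1 = compute_activity_map(movie, (0.0, 4.0), (4.0, 6.0))
    amap2 = compute_activity_map(movie.replaced(movie.data * 3.7), (0.0, 4.0), (4.0, 6.0))
    assert np.allclose(amap1.dff, amap2.dff, atol=1e-12)
    assert np.array_equal(amap1.responsive, amap2.responsive)


def test_activity_map_zero_baseline_invalid():
    data = np.ones((10, 8, 8))
    data[:, 0, 0] = 0.0
    movie = MovieStack(data, frame_period=1.0)
    amap = compute_activity_map(movie, (0.0, 4.0), (5.0, 9.0))
    assert not amap.valid[0, 0]
    assert np.isnan(amap.dff[0, 0])
    assert amap.valid[1:, :].all()


def test_activity_map_respects_kept_mask():
    # a huge artifact inside the stimulus window is neutralized when QC drops it
    data = np.full((12, 6, 6), 10.0)
    data[8] = 1000.0
    movie = MovieStack(data, frame_period=1.0)
    kept = np.ones(12, dtype=bool)
    kept[8] = False
    amap = compute_activity_map(movie, (0.0, 5.0), (7.0, 11.0), kept=kept)
    assert np.allclose(amap.dff, 0.0)
    assert not amap.responsive.any()


def test_activity_map_window_validation():
    movie = MovieStack(np.ones((10, 6, 6)), frame_period=1.0)
    with pytest.raises(ValueError):
        compute_activity_map(movie, (0.0, 6.0), (5.0, 9.0))  # overlapping windows
    with pytest.raises(ValueError):
        compute_activity_map(movie, (0.0, 1.0), (5.0, 9.0))  # single pre frame


def test_activity_map_noise_false_positive_rate_low(rng):
    movie, _ = _random_movie(rng, T=60, spatial=(32, 32), noise_sd=2.0)
    amap = compute_activity_map(movie, (0.0, 6.0), (8.0, 10.0))
    # dF needs > 2 pre-stimulus SDs: z approx 5.5 under pure noise
    assert amap.responsive.mean() < 0.01


def test_roi_trace_and_peak_noiseless(rng):
    spatial = (16, 16)
    baseline = synthetic.random_baseline_image(spatial, rng)
    amp = 0.6
    params = synthetic.MovieParams(
        shape=(50,) + spatial,
        frame_period=0.2,
        baseline_image=baseline,
        response_maps={"MCH": np.full(spatial, amp)},
        stim_windows={"MCH": (4.0, 8.0)},
        seed=0,
    )
    movie, truth = synthetic.simulate_movie(params)
    trace = roi_dff_trace(movie, np.ones(spatial, dtype=bool), (0.0, 4.0))
    # a spatially uniform response makes the ROI trace exactly amp * k(t)
    k = synthetic.response_kinetics(movie.frame_times, (4.0, 8.0), params.tau_rise, params.tau_decay)
    assert np.max(np.abs(trace.dff - amp * k)) < 1e-12
    assert peak_response(trace, (4.0, 8.0)) == pytest.approx(amp * truth.peak_k["MCH"], abs=1e-12)


def test_roi_trace_validation(rng):
    movie, _ = _random_movie(rng, T=10)
    with pytest.raises(ValueError):
        roi_dff_trace(movie, np.zeros(movie.data.shape[1:], dtype=bool), (0.0, 1.0))
    with pytest.raises(ValueError):
        roi_dff_trace(movie, np.ones((3, 3), dtype=bool), (0.0, 1.0))
    trace = roi_dff_trace(movie, np.ones(movie.data.shape[1:], dtype=bool), (0.0, 1.0))
    with pytest.raises(ValueError):
        peak_response(trace, (100.0, 101.0))


def test_frames_in_half_open_by_start_time():
    movie = MovieStack(np.ones((10, 4, 4)), frame_period=1.0)
    sel = movie.frames_in((2.0, 5.0))
    assert np.array_equal(np.flatnonzero(sel), [2, 3, 4])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
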