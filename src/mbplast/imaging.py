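"""Calcium-movie preprocessing and per-pixel/per-ROI response measurement.

The pipeline stages, in the order they are normally applied:

1. :func:`correct_motion_xy` — rigid integer XY registration, estimated on a
   Z-collapsed, heavily smoothed copy and applied to the raw movie.
2. :func:`correct_motion_z` — per-volume integer plane offsets maximizing the
   correlation with the time-average volume (volumetric movies only).
3. :func:`qc_discard_frames` — drop frames that decorrelate from the baseline
   image (sudden large axial movements).
4. :func:`smooth_for_analysis` — 5x5 spatial Gaussian (sigma 2 px) before any
   dF/F computation.
5. :func:`compute_activity_map` / :func:`roi_dff_trace` / :func:`peak_response`.

Conventions: windows are half-open ``[start, end)`` in seconds and a frame
belongs to a window by its start time; pixels are 0-based ``(row, col)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import median_abs_deviation

__all__ = [
    "MovieStack",
    "ActivityMap",
    "RoiTrace",
    "XYMotionResult",
    "ZMotionResult",
    "QCResult",
    "correct_motion_xy",
    "correct_motion_z",
    "qc_discard_frames",
    "smooth_for_analysis",
    "compute_activity_map",
    "roi_dff_trace",
    "peak_response",
]


@dataclass
class MovieStack:
    """T×(Z×)Y×X fluorescence movie with acquisition metadata.

    ``stim_windows`` maps a stimulus name to a half-open ``(start, end)``
    interval in seconds.
    """

    data: np.ndarray
    frame_period: float
    stim_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("movie must be T×Y×X or T×Z×Y×X")
        if np.any(self.data < 0):
            raise ValueError("negative intensities")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        dur = self.duration
        for name, (a, b) in self.stim_windows.items():
            if not (0 <= a < b <= dur):
                raise ValueError(f"stimulus window {name!r} = [{a}, {b}) outside movie duration {dur}")

    @property
    def is_volumetric(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_period

    @property
    def frame_times(self) -> np.ndarray:
        """Start time of each frame (s)."""
        return np.arange(self.n_frames) * self.frame_period

    def frames_in(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of frames whose start time lies in [start, end)."""
        t = self.frame_times
        return (t >= window[0]) & (t < window[1])

    def replaced(self, data: np.ndarray, **meta) -> "MovieStack":
        m = dict(self.meta)
        m.update(meta)
        return MovieStack(data, self.frame_period, dict(self.stim_windows), m)


@dataclass
class ActivityMap:
    """Per-pixel stimulus-evoked dF/F with the responsiveness mask.

    ``dff`` is NaN at pixels with non-positive baseline (``valid`` False);
    ``responsive`` marks pixels whose dF exceeded ``sd_factor`` times the
    per-pixel pre-stimulus SD.
    """

    dff: np.ndarray
    responsive: np.ndarray
    baseline: np.ndarray
    prestim_sd: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class RoiTrace:
    """dF/F time course of the ROI-mean fluorescence on QC-kept frames."""

    roi_name: str
    t: np.ndarray
    dff: np.ndarray
    kept_frames: np.ndarray  # indices into the original movie


@dataclass
class XYMotionResult:
    movie: MovieStack
    shifts: np.ndarray  # (T, 2) applied (dy, dx) per frame
    clamped: np.ndarray  # frames whose best shift hit the search boundary
    constant_frames: np.ndarray  # frames with undefined correlation


@dataclass
class ZMotionResult:
    movie: MovieStack
    offsets: np.ndarray  # (T,) applied plane offset per time point
    padded: np.ndarray  # time points where out-of-range planes were edge-padded


@dataclass
class QCResult:
    kept: np.ndarray  # boolean per frame
    correlations: np.ndarray
    threshold: float
    excessive_discard: bool  # >50% of frames dropped


def _spatial_collapse(data: np.ndarray) -> np.ndarray:
    """Mean-project the Z axis of a volumetric movie; identity otherwise."""
    return data.mean(axis=1) if data.ndim == 4 else data


def _best_circular_shift(ref: np.ndarray, frame: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (dy, dx) with |dy|,|dx| <= max_shift maximizing the Pearson
    correlation of ``np.roll(frame, (dy, dx))`` with ``ref``.

    Under circular shifts the shifted frame's mean and variance are
    shift-invariant, so the Pearson maximizer equals the raw circular
    cross-correlation maximizer, which is computed exactly via FFT.
    Ties break toward the smallest |dy|+|dx|, then lexicographically.
    """
    cc = np.fft.irfft2(np.fft.rfft2(ref) * np.conj(np.fft.rfft2(frame)), s=ref.shape)
    offs = np.arange(-max_shift, max_shift + 1)
    sub = cc[np.ix_(offs % ref.shape[0], offs % ref.shape[1])]
    # order candidates so np.argmax's first-wins rule implements the tie rule
    order = sorted(
        ((dyi, dxi) for dyi in range(len(offs)) for dxi in range(len(offs))),
        key=lambda ij: (abs(offs[ij[0]]) + abs(offs[ij[1]]), offs[ij[0]], offs[ij[1]]),
    )
    vals = np.array([sub[i, j] for i, j in order])
    # first candidate (in tie order) attaining the maximum within FFT slack
    vmax = vals.max()
    for (i, j), v in zip(order, vals):
        if v >= vmax - 1e-9 * max(1.0, abs(vmax)):
            return int(offs[i]), int(offs[j])
    raise AssertionError("unreachable")


def correct_motion_xy(
    movie: MovieStack,
    smooth_sd: float = 4.0,
    max_shift: int = 10,
    reference: str = "mean",
) -> XYMotionResult:
    """Rigid integer XY motion correction.

    Displacements are estimated on the Z-collapsed movie after Gaussian
    smoothing (``smooth_sd`` px) against a reference image (the mean frame
    by default, or the first frame), then applied — as circular integer
    shifts, no interpolation — to the original unsmoothed movie.
    """
    ny, nx = movie.data.shape[-2:]
    if not max_shift < min(ny, nx) / 4:
        raise ValueError("max_shift must be below a quarter of the frame size")
    proj = _spatial_collapse(movie.data)
    # periodic smoothing commutes exactly with the circular shifts being
    # estimated, so pre-smoothing cannot bias the shift estimate
    smoothed = ndimage.gaussian_filter(proj, sigma=(0, smooth_sd, smooth_sd), mode="wrap")
    ref = smoothed.mean(axis=0) if reference == "mean" else smoothed[0]
    T = movie.n_frames
    shifts = np.zeros((T, 2), dtype=int)
    clamped = np.zeros(T, dtype=bool)
    constant = np.zeros(T, dtype=bool)
    ref_c = ref - ref.mean()
    for t in range(T):
        fr = smoothed[t]
        if np.ptp(fr) == 0 or np.ptp(ref) == 0:
            constant[t] = True
            continue
        dy, dx = _best_circular_shift(ref_c, fr - fr.mean(), max_shift)
        shifts[t] = (dy, dx)
        clamped[t] = abs(dy) == max_shift or abs(dx) == max_shift
    if constant.any():
        warnings.warn("constant frames encountered; their XY shift was set to 0")
    out = np.empty_like(movie.data)
    for t in range(T):
        out[t] = np.roll(movie.data[t], tuple(shifts[t]), axis=(-2, -1))
    return XYMotionResult(
        movie.replaced(out, xy_shifts=shifts.tolist()),
        shifts,
        clamped,
        constant,
    )


def _apply_plane_offset(vol: np.ndarray, offset: int) -> np.ndarray:
    """Shift planes so corrected plane j = original plane j − offset,
    clamping out-of-range indices to the edge plane."""
    z = vol.shape[0]
    idx = np.clip(np.arange(z) - offset, 0, z - 1)
    return vol[idx]


def correct_motion_z(movie: MovieStack, max_offset: int | None = None) -> ZMotionResult:
    """Integer Z-plane correction against the time-average volume.

    For each time point the plane offset maximizing the pixel-by-pixel
    Pearson correlation between the offset volume and the average volume
    is applied; out-of-range planes are padded with the edge plane.
    Ties resolve to the smallest-magnitude offset.
    """
    if not movie.is_volumetric or movie.data.shape[1] < 2:
        warnings.warn("Z correction skipped: movie has fewer than 2 planes")
        return ZMotionResult(movie, np.zeros(movie.n_frames, dtype=int), np.zeros(movie.n_frames, bool))
    z = movie.data.shape[1]
    if max_offset is None:
        max_offset = z - 1
    ref = movie.data.mean(axis=0).ravel()
    ref_c = ref - ref.mean()
    ref_n = np.sqrt((ref_c**2).sum())
    candidates = sorted(range(-max_offset, max_offset + 1), key=lambda o: (abs(o), o))
    T = movie.n_frames
    offsets = np.zeros(T, dtype=int)
    out = np.empty_like(movie.data)
    for t in range(T):
        best, best_r = 0, -np.inf
        for o in candidates:
            v = _apply_plane_offset(movie.data[t], o).ravel()
            vc = v - v.mean()
            denom = ref_n * np.sqrt((vc**2).sum())
            r = (ref_c @ vc) / denom if denom > 0 else -np.inf
            if r > best_r + 1e-12:
                best, best_r = o, r
        offsets[t] = best
        out[t] = _apply_plane_offset(movie.data[t], best)
    padded = offsets != 0
    return ZMotionResult(movie.replaced(out, z_offsets=offsets.tolist()), offsets, padded)


def qc_discard_frames(
    movie: MovieStack,
    baseline_image: np.ndarray,
    threshold: float | str = "auto",
    k: float = 5.0,
) -> QCResult:
    """Drop frames whose correlation with the baseline image collapses.

    Each frame (full volume for volumetric movies) is Pearson-correlated
    with ``baseline_image``; frames strictly below the threshold are
    discarded.  ``threshold='auto'`` places the cut at
    ``median − k·MAD`` of the correlation series, with the MAD on the
    normal-consistent scale (×1.4826) so ``k`` counts robust SDs.
    """
    b = np.asarray(baseline_image, dtype=float).ravel()
    bc = b - b.mean()
    bn = np.sqrt((bc**2).sum())
    if bn == 0:
        raise ValueError("baseline image is constant; QC correlation undefined")
    T = movie.n_frames
    corr = np.empty(T)
    flat = movie.data.reshape(T, -1)
    fc = flat - flat.mean(axis=1, keepdims=True)
    fn = np.sqrt((fc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (fc @ bc) / (fn * bn)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if threshold == "auto":
        med = float(np.median(corr))
        mad = float(median_abs_deviation(corr, scale="normal"))
        thr = med - k * mad
    else:
        thr = float(threshold)
        if not -1 <= thr <= 1:
            raise ValueError("threshold must lie in [-1, 1] or be 'auto'")
    kept = corr >= thr
    excessive = kept.mean() < 0.5
    if excessive:
        warnings.warn(f"QC discarded {100 * (1 - kept.mean()):.0f}% of frames")
    return QCResult(kept, corr, thr, excessive)


def smooth_for_analysis(movie: MovieStack, sigma: float = 2.0, radius: int = 2) -> MovieStack:
    """Per-frame spatial Gaussian smoothing before dF/F computation.

    Defaults give a 5x5 kernel (sigma 2 px truncated at radius 2) whose
    truncated mass is renormalized to 1; borders use reflection padding.
    """
    nd = movie.data.ndim
    sig = (0,) * (nd - 2) + (sigma, sigma)
    truncate = radius / sigma
    out = ndimage.gaussian_filter(movie.data, sigma=sig, truncate=truncate, mode="reflect")
    return movie.replaced(out, smoothed=dict(sigma=sigma, radius=radius))


def _window_frames(movie: MovieStack, window: tuple[float, float], kept: np.ndarray | None) -> np.ndarray:
    sel = movie.frames_in(window)
    if kept is not None:
        sel = sel & np.asarray(kept, dtype=bool)
    return sel


def compute_activity_map(
    movie: MovieStack,
    prestim_window: tuple[float, float],
    stim_window: tuple[float, float],
    sd_factor: float = 2.0,
    kept: np.ndarray | None = None,
) -> ActivityMap:
    """Per-pixel stimulus-evoked dF/F and the 2-SD responsiveness mask.

    Baseline is the mean over pre-stimulus kept frames; dF is the
    stimulus-mean minus the baseline; dF/F = dF / baseline.  A pixel is
    responsive when dF exceeds ``sd_factor`` times its pre-stimulus SD
    (sample SD over time, floored at a machine-epsilon scale so noiseless
    synthetic input behaves).  Pixels with non-positive baseline are
    excluded (``valid`` False, dff NaN).
    """
    if prestim_window[1] > stim_window[0]:
        raise ValueError("pre-stimulus window must precede the stimulus window")
    pre_sel = _window_frames(movie, prestim_window, kept)
    stim_sel = _window_frames(movie, stim_window, kept)
    if pre_sel.sum() < 2 or stim_sel.sum() < 2:
        raise ValueError("each window needs at least 2 kept frames")
    pre = movie.data[pre_sel]
    baseline = pre.mean(axis=0)
    prestim_sd = pre.std(axis=0, ddof=1)
    stim_mean = movie.data[stim_sel].mean(axis=0)
    valid = baseline > 0
    df = stim_mean - baseline
    with np.errstate(invalid="ignore", divide="ignore"):
        dff = np.where(valid, df / baseline, np.nan)
    sd_floor = np.sqrt(np.finfo(float).eps) * max(1.0, float(np.nanmax(baseline, initial=1.0)))
    sd_eff = np.maximum(prestim_sd, sd_floor)
    responsive = valid & (df > sd_factor * sd_eff)
    return ActivityMap(
        dff=dff,
        responsive=responsive,
        baseline=baseline,
        prestim_sd=prestim_sd,
        valid=valid,
        meta=dict(
            prestim_window=tuple(prestim_window),
            stim_window=tuple(stim_window),
            sd_factor=sd_factor,
            n_pre=int(pre_sel.sum()),
            n_stim=int(stim_sel.sum()),
        ),
    )


def roi_dff_trace(
    movie: MovieStack,
    roi_mask: np.ndarray,
    prestim_window: tuple[float, float],
    kept: np.ndarray | None = None,
    roi_name: str = "roi",
) -> RoiTrace:
    """dF/F(t) of the ROI-mean fluorescence, on QC-kept frames only."""
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != movie.data.shape[1:]:
        raise ValueError("ROI mask shape must match the movie's spatial shape")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    keep = np.ones(movie.n_frames, dtype=bool) if kept is None else np.asarray(kept, bool)
    f = movie.data[:, mask].mean(axis=1)
    pre_sel = _window_frames(movie, prestim_window, keep)
    if pre_sel.sum() < 1:
        raise ValueError("no kept frames in the pre-stimulus window")
    f0 = f[pre_sel].mean()
    if f0 <= 0:
        raise ValueError("ROI baseline fluorescence is non-positive")
    idx = np.flatnonzero(keep)
    return RoiTrace(
        roi_name=roi_name,
        t=movie.frame_times[idx],
        dff=(f[idx] - f0) / f0,
        kept_frames=idx,
    )


def peak_response(trace: RoiTrace, window: tuple[float, float]) -> float:
    """Maximum dF/F of the trace within a half-open time window."""
    sel = (trace.t >= window[0]) & (trace.t < window[1])
    if not sel.any():
        raise ValueError("no kept frames inside the requested window")
    return float(trace.dff[sel].max())
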