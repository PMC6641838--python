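"""Population-coding statistics on activity maps.

* :func:`population_sparseness` — the Vinje–Gallant-form population
  sparseness of a pixel response vector r (nonnegative, N ≥ 2):

      SP = [1 − ((Σ rᵢ / N)² / (Σ rᵢ² / N))] / (1 − 1/N)

  0 for a uniform population, 1 for a one-hot population.
* :func:`align_by_baseline` / :func:`interodor_correlation` — rigid
  integer alignment of two maps on their baseline images, followed by the
  Pearson correlation of the masked dF/F "odor vectors".
* :func:`response_ratio` — trained:untrained peak-response ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import threshold_otsu

from .imaging import ActivityMap

__all__ = [
    "SparsenessResult",
    "CorrelationResult",
    "population_sparseness",
    "align_by_baseline",
    "interodor_correlation",
    "response_ratio",
    "mbon_ratio_table",
]


@dataclass
class SparsenessResult:
    SP: float
    N: int
    r: np.ndarray  # the response vector actually used (audit trail)


@dataclass
class CorrelationResult:
    r_pearson: float
    shift_applied: tuple[int, int]
    n_pixels: int
    baseline_threshold: float


def _response_vector(
    amap: ActivityMap | np.ndarray,
    mask: np.ndarray | None,
    responsive_only: bool,
) -> np.ndarray:
    if isinstance(amap, ActivityMap):
        sel = amap.valid if mask is None else (np.asarray(mask, bool) & amap.valid)
        r = np.where(amap.responsive, amap.dff, 0.0)[sel]
        if responsive_only:
            r = r[amap.responsive[sel]]
    else:
        arr = np.asarray(amap, dtype=float)
        r = arr[np.asarray(mask, bool)] if mask is not None else arr.ravel()
    return np.clip(np.nan_to_num(r, nan=0.0), 0.0, None)


def population_sparseness(
    amap: ActivityMap | np.ndarray,
    mask: np.ndarray | None = None,
    responsive_only: bool = False,
) -> SparsenessResult:
    """Population sparseness SP in [0, 1] of the masked dF/F values.

    Non-responsive pixels contribute 0 and negative dF/F is clipped to 0
    (the formula guarantees SP in [0, 1] only for nonnegative r).  An
    all-zero response vector yields SP = 0 by convention.
    """
    r = _response_vector(amap, mask, responsive_only)
    n = r.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 pixels")
    sum_r = r.sum()
    sum_r2 = (r**2).sum()
    if sum_r2 == 0:
        return SparsenessResult(0.0, n, r)
    sp = (1.0 - (sum_r / n) ** 2 / (sum_r2 / n)) / (1.0 - 1.0 / n)
    return SparsenessResult(float(sp), n, r)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        return np.nan
    return float((ac @ bc) / denom)


def align_by_baseline(
    map_a: ActivityMap, map_b: ActivityMap, max_shift: int = 10
) -> tuple[int, int]:
    """Integer (dy, dx) to apply to map B maximizing the Pearson
    correlation of the two baseline images.

    Exhaustive search within ±max_shift; ties break toward the smallest
    |dy| + |dx|, then lexicographically.  A constant baseline yields
    (0, 0) with a warning.
    """
    a, b = map_a.baseline, map_b.baseline
    if a.shape != b.shape:
        raise ValueError("baselines must share a shape")
    if a.ndim != 2:
        raise ValueError("alignment supports 2-D maps only")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant baseline; alignment shift set to (0, 0)")
        return (0, 0)
    candidates = sorted(
        ((dy, dx) for dy in range(-max_shift, max_shift + 1) for dx in range(-max_shift, max_shift + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]),
    )
    best, best_r = (0, 0), -np.inf
    for dy, dx in candidates:
        r = _pearson(a.ravel(), np.roll(b, (dy, dx), axis=(0, 1)).ravel())
        if np.isfinite(r) and r > best_r + 1e-12:
            best, best_r = (dy, dx), r
    return best


def interodor_correlation(
    map_a: ActivityMap,
    map_b: ActivityMap,
    baseline_threshold: float | str = "otsu",
    max_shift: int = 10,
) -> CorrelationResult:
    """Pearson correlation of two odors' activity-map vectors.

    Map B is first rigidly aligned to map A on the baseline images; a
    baseline-fluorescence threshold (Otsu's threshold on the mean of the
    two aligned baselines by default, or an explicit number) masks out
    pixels with no baseline signal, and the masked dF/F values of the two
    maps are flattened into vectors and correlated.
    """
    if map_a.dff.shape != map_b.dff.shape:
        raise ValueError("maps must share a shape")
    shift = align_by_baseline(map_a, map_b, max_shift=max_shift)
    base_b = np.roll(map_b.baseline, shift, axis=(0, 1))
    dff_b = np.roll(map_b.dff, shift, axis=(0, 1))
    valid_b = np.roll(map_b.valid, shift, axis=(0, 1))
    if baseline_threshold == "otsu":
        thr = float(threshold_otsu(0.5 * (map_a.baseline + base_b)))
    else:
        thr = float(baseline_threshold)
    mask = (map_a.baseline > thr) & (base_b > thr) & map_a.valid & valid_b
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"baseline mask keeps only {n} pixels (need >= 3)")
    r = _pearson(map_a.dff[mask], dff_b[mask])
    return CorrelationResult(r_pearson=r, shift_applied=shift, n_pixels=n, baseline_threshold=thr)


def response_ratio(resp_num: float, resp_den: float) -> float:
    """Plain trained:untrained response ratio; nonpositive denominators
    are an error (the fly must be flagged, never silently dropped)."""
    if resp_den <= 0:
        raise ValueError(f"nonpositive denominator response {resp_den}")
    return float(resp_num) / float(resp_den)


def mbon_ratio_table(
    table: pd.DataFrame, num_odor: str, den_odor: str, value_col: str = "peak_dff"
) -> pd.DataFrame:
    """Per-fly response ratios from a long-format MBON table.

    Returns one row per fly (fly_id, group, ratio, flagged); flies with a
    nonpositive denominator get ratio NaN and flagged True.
    """
    wide = table.pivot_table(index=["fly_id", "group"], columns="odor", values=value_col)
    out = []
    for (fly, group), row in wide.iterrows():
        den = row[den_odor]
        flagged = not den > 0
        out.append(
            dict(
                fly_id=fly,
                group=group,
                ratio=np.nan if flagged else response_ratio(row[num_odor], den),
                flagged=flagged,
            )
        )
    return pd.DataFrame(out)
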