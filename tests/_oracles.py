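"""Independent brute-force oracles used by the test suite.

Each oracle implements the textbook definition as directly (and slowly)
as possible, sharing no code with the package implementation, so that
agreement is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    ac = a - a.mean()
    bc = b - b.mean()
    den = math.sqrt(float((ac**2).sum()) * float((bc**2).sum()))
    return float(ac @ bc) / den if den > 0 else float("nan")


def best_shift_bruteforce(ref: np.ndarray, frame: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Pearson-maximizing circular (dy, dx); ties -> smallest |dy|+|dx|, then lexicographic."""
    best, best_r = None, -np.inf
    cands = sorted(
        (
            (dy, dx)
            for dy in range(-max_shift, max_shift + 1)
            for dx in range(-max_shift, max_shift + 1)
        ),
        key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]),
    )
    for dy, dx in cands:
        r = pearson(ref, np.roll(frame, (dy, dx), axis=(0, 1)))
        if r > best_r + 1e-9:
            best, best_r = (dy, dx), r
    return best


def gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_dense(img: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    """Direct 2-D convolution with the separable truncated Gaussian,
    symmetric (edge-mirroring) boundary handling."""
    k1 = gaussian_kernel_1d(sigma, radius)
    k2 = np.outer(k1, k1)
    pad = np.pad(img, radius, mode="symmetric")
    ny, nx = img.shape
    out = np.empty_like(img, dtype=float)
    for i in range(ny):
        for j in range(nx):
            out[i, j] = (pad[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * k2).sum()
    return out


def mann_whitney_exact_enum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data).

    Returns (U of sample a, p).  p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1 -- the standard exact two-sided definition.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1  # 1-based ranks, no ties
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    # null distribution of U over all rank assignments
    all_ranks = range(1, n1 + n2 + 1)
    us = [
        sum(c) - n1 * (n1 + 1) / 2 for c in itertools.combinations(all_ranks, n1)
    ]
    us = np.asarray(us, float)
    total = us.size
    p_le = (us <= u_obs).sum() / total
    p_ge = (us >= u_obs).sum() / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def rankdata_avg(x: np.ndarray) -> np.ndarray:
    """Average ranks (midranks for ties), written independently."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h_bruteforce(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank-variance identity:
    H = (N - 1) * sum n_i (rbar_i - rbar)^2 / sum (r_ij - rbar)^2."""
    pooled = np.concatenate(groups)
    ranks = rankdata_avg(pooled)
    n_total = pooled.size
    rbar = ranks.mean()
    num = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        num += g.size * (r.mean() - rbar) ** 2
        start += g.size
    den = ((ranks - rbar) ** 2).sum()
    return (n_total - 1) * num / den


def mixed_anova_ss_bruteforce(df, dv, within, between, subject):
    """Partitioned sums of squares and F ratios of a balanced two-way
    mixed design (one between-subjects factor, one within-subjects factor),
    from the cell/marginal-means decomposition."""
    grand = df[dv].mean()
    k = df[between].nunique()
    w = df[within].nunique()
    subj_means = df.groupby(subject)[dv].mean()
    n_per = df.groupby(between)[subject].nunique()
    n_subj = int(n_per.sum())
    g_means = df.groupby(between)[dv].mean()
    w_means = df.groupby(within)[dv].mean()
    gw_means = df.groupby([between, within])[dv].mean()
    ss_between_subj = w * ((subj_means - grand) ** 2).sum()
    ss_group = sum(n_per[g] * w * (g_means[g] - grand) ** 2 for g in g_means.index)
    ss_subj_within = ss_between_subj - ss_group
    ss_within_factor = sum(n_subj * (w_means[lvl] - grand) ** 2 for lvl in w_means.index)
    ss_inter = sum(
        n_per[g] * (gw_means[(g, lvl)] - g_means[g] - w_means[lvl] + grand) ** 2
        for g in g_means.index
        for lvl in w_means.index
    )
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_within_factor - ss_inter
    ms_group = ss_group / (k - 1)
    ms_subj = ss_subj_within / (n_subj - k)
    ms_within = ss_within_factor / (w - 1)
    ms_inter = ss_inter / ((k - 1) * (w - 1))
    ms_err = ss_err / ((n_subj - k) * (w - 1))
    return dict(
        ss_group=float(ss_group),
        ss_within=float(ss_within_factor),
        ss_interaction=float(ss_inter),
        f_group=float(ms_group / ms_subj),
        f_within=float(ms_within / ms_err),
        f_interaction=float(ms_inter / ms_err),
    )


def sparseness_direct(r: np.ndarray) -> float:
    """Direct evaluation of the population-sparseness formula."""
    r = np.asarray(r, float)
    n = r.size
    mean_sq = (r.sum() / n) ** 2
    sq_mean = (r**2).sum() / n
    return (1.0 - mean_sq / sq_mean) / (1.0 - 1.0 / n)
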