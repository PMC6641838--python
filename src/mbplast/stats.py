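"""Group-comparison and power procedures for behavior scores, peak
responses, response ratios and qPCR fold changes.

Implemented tests mirror the figure-legend statistics of the assay:
Kruskal–Wallis with Dunn's pairwise comparisons, Mann–Whitney (exact for
small tie-free samples), one-sample t with Bonferroni correction,
two-way mixed-design (repeated-measures) ANOVA with Holm–Šídák pairwise
comparisons, Monte-Carlo power for two-sample designs, and ΔΔCt fold
changes.  Every stochastic procedure takes an explicit seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PairwiseComparison",
    "PowerResult",
    "kruskal_wallis_dunn",
    "mann_whitney",
    "one_sample_t_bonferroni",
    "rm_anova_holm_sidak",
    "power_two_sample",
    "ddct_fold_change",
]


@dataclass
class PairwiseComparison:
    a: str
    b: str
    statistic: float
    p_raw: float
    p_adj: float


@dataclass
class TestResult:
    test: str
    statistic: float
    p_raw: float
    n: dict
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    adjust_method: str = ""
    method: str = ""
    notes: list[str] = field(default_factory=list)
    anova: pd.DataFrame | None = None


def _groups_from_table(table: pd.DataFrame, group_col: str, value_col: str) -> dict[str, np.ndarray]:
    return {
        str(g): np.asarray(sub[value_col], dtype=float)
        for g, sub in table.groupby(group_col, sort=False)
    }


def kruskal_wallis_dunn(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]] | None = None,
    group_col: str = "group",
    value_col: str = "value",
) -> TestResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise z tests.

    ``comparisons`` restricts Dunn's family (default: all pairs); the
    adjustment is Dunn's procedure — a Bonferroni correction of the
    pairwise normal p values over the requested family.
    """
    groups = _groups_from_table(table, group_col, value_col)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = list(groups)
    values = [groups[g] for g in names]
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*values)
    # Dunn's z on mean ranks with tie correction
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    splits = np.cumsum([len(v) for v in values])[:-1]
    mean_ranks = {g: r.mean() for g, r in zip(names, np.split(ranks, splits))}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = comparisons or list(itertools.combinations(names, 2))
    m = len(pairs)
    pw = []
    for a, b in pairs:
        se = math.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        pw.append(PairwiseComparison(a, b, z, p_raw, min(1.0, m * p_raw)))
    return TestResult(
        test="kruskal-wallis",
        statistic=float(h),
        p_raw=float(p),
        n={g: len(v) for g, v in groups.items()},
        pairwise=pw,
        adjust_method="dunn (bonferroni over requested family)",
        method="tie-corrected H, chi-square approximation",
    )


def mann_whitney(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test.

    Exact p when both samples have <= 8 observations and the pooled data
    are tie-free; otherwise the normal approximation with tie and
    continuity corrections.  The method used is recorded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples need >= 1 observation")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and max(a.size, b.size) <= 8
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return TestResult(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_raw=float(min(1.0, res.pvalue)),
        n={"a": a.size, "b": b.size},
        method=method,
    )


def one_sample_t_bonferroni(
    values_by_region: dict[str, np.ndarray], mu: float = 0.0, m: int | None = None
) -> TestResult:
    """One-sample t tests against ``mu`` per region, Bonferroni-adjusted.

    Zero-variance samples are flagged: p = 0 when the mean differs from
    mu, p = 1 otherwise.
    """
    m = m if m is not None else len(values_by_region)
    pw = []
    notes = []
    for region, vals in values_by_region.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"region {region!r} needs >= 2 values")
        if v.std(ddof=1) == 0:
            p = 1.0 if v.mean() == mu else 0.0
            t = 0.0 if v.mean() == mu else math.inf * np.sign(v.mean() - mu)
            notes.append(f"zero variance in {region!r}")
        else:
            t, p = sps.ttest_1samp(v, mu)
        pw.append(PairwiseComparison(region, f"mu={mu}", float(t), float(p), min(1.0, m * float(p))))
    return TestResult(
        test="one-sample-t",
        statistic=float("nan"),
        p_raw=float("nan"),
        n={r: len(np.asarray(v)) for r, v in values_by_region.items()},
        pairwise=pw,
        adjust_method=f"bonferroni (m={m})",
        notes=notes,
    )


def rm_anova_holm_sidak(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "within",
    between: str = "group",
    subject: str = "unit_id",
    comparisons: str = "between-at-each-within",
) -> TestResult:
    """Two-way mixed-design ANOVA with Holm–Šídák pairwise comparisons.

    One repeated (within-unit) factor and one grouping factor; units
    missing a within level are dropped with a log note.  The default
    pairwise family compares the groups at each within level
    (independent t tests); Holm–Šídák step-down adjustment with enforced
    monotonicity is applied over the family.
    """
    df = table[[subject, between, within, dv]].copy()
    n_levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == n_levels].index
    dropped = sorted(set(df[subject]) - set(complete))
    notes = [f"dropped incomplete units: {dropped}"] if dropped else []
    df = df[df[subject].isin(complete)]
    aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between, subject=subject)
    inter = aov[aov["Source"] == "Interaction"]
    f_inter = float(inter["F"].iloc[0]) if len(inter) else float("nan")
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p_inter = float(inter[p_col].iloc[0]) if len(inter) else float("nan")

    pw = []
    if comparisons == "between-at-each-within":
        raws = []
        labels = []
        for lvl, sub in df.groupby(within, sort=False):
            gs = _groups_from_table(sub, between, dv)
            if len(gs) != 2:
                raise ValueError("default pairwise family needs exactly 2 groups")
            (ga, va), (gb, vb) = gs.items()
            t, p = sps.ttest_ind(va, vb)
            raws.append(float(p))
            labels.append((f"{ga} vs {gb} @ {lvl}", float(t)))
        _, p_adj, _, _ = multipletests(raws, method="holm-sidak")
        for (lab, t), p_r, p_a in zip(labels, raws, p_adj):
            a_lab, b_lab = lab.split(" vs ", 1)
            pw.append(PairwiseComparison(a_lab, b_lab, t, p_r, float(p_a)))
    return TestResult(
        test="rm-anova (mixed design)",
        statistic=f_inter,
        p_raw=p_inter,
        n={"units": int(df[subject].nunique())},
        pairwise=pw,
        adjust_method="holm-sidak",
        notes=notes,
        anova=aov,
    )


@dataclass
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_sims: int
    alpha: float


def power_two_sample(
    sampler,
    n_per_group: int,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    test: str = "mann-whitney",
) -> PowerResult:
    """Monte-Carlo power of a two-sample test under an effect model.

    ``sampler(rng, n) -> (a, b)`` draws one simulated experiment.  The
    power is the fraction of simulations rejecting at ``alpha``; a 95%
    binomial (Wilson) CI is reported.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a, b = sampler(rng, n_per_group)
        if test == "mann-whitney":
            p = mann_whitney(a, b).p_raw
        elif callable(test):
            p = test(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        rejections += p < alpha
    power = rejections / n_sims
    z = sps.norm.ppf(0.975)
    denom = 1 + z**2 / n_sims
    center = (power + z**2 / (2 * n_sims)) / denom
    half = z * math.sqrt(power * (1 - power) / n_sims + z**2 / (4 * n_sims**2)) / denom
    return PowerResult(power, center - half, center + half, n_sims, alpha)


def ddct_fold_change(
    ct_table: pd.DataFrame,
    calibrator_sample: str,
    sample_col: str = "sample",
    target_col: str = "target_ct",
    reference_col: str = "reference_ct",
) -> pd.DataFrame:
    """ΔΔCt relative quantification against a reference gene and calibrator.

    Technical replicates are averaged by mean Ct; per sample
    ΔCt = Ct_target − Ct_reference, ΔΔCt = ΔCt − ΔCt_calibrator, and
    fold = 2^(−ΔΔCt).  Samples missing a reference Ct are dropped with a
    log column note.
    """
    df = ct_table.copy()
    missing = df[df[reference_col].isna()][sample_col].unique().tolist()
    df = df.dropna(subset=[reference_col, target_col])
    agg = df.groupby(sample_col)[[target_col, reference_col]].mean()
    if calibrator_sample not in agg.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
    dct = agg[target_col] - agg[reference_col]
    ddct = dct - dct.loc[calibrator_sample]
    out = pd.DataFrame(
        {
            "sample": agg.index,
            "delta_ct": dct.values,
            "ddct": ddct.values,
            "fold_change": np.power(2.0, -ddct.values),
        }
    ).reset_index(drop=True)
    out.attrs["dropped_samples"] = missing
    return out
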