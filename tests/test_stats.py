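"""Unit tests for the hypothesis tests, power and ΔΔCt procedures."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import _oracles
from mbplast.stats import (
    ddct_fold_change,
    kruskal_wallis_dunn,
    mann_whitney,
    one_sample_t_bonferroni,
    power_two_sample,
    rm_anova_holm_sidak,
)


def _long_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = [dict(group=g, value=float(v)) for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def test_mw_exact_matches_enumeration_small(rng):
    for _ in range(10):
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        a = rng.normal(size=n1)
        b = rng.normal(size=n2) + rng.normal()
        res = mann_whitney(a, b)
        assert res.method == "exact"
        u_oracle, p_oracle = _oracles.mann_whitney_exact_enum(a, b)
        assert res.p_raw == pytest.approx(p_oracle, abs=1e-12)


def test_mw_u_statistic_identity(rng):
    a, b = rng.normal(size=6), rng.normal(size=5)
    u_ab = mann_whitney(a, b).statistic
    u_ba = mann_whitney(b, a).statistic
    assert u_ab + u_ba == pytest.approx(len(a) * len(b))


def test_mw_falls_back_to_asymptotic():
    a = np.arange(20.0)
    b = np.arange(20.0) + 0.5
    assert mann_whitney(a, b).method == "asymptotic"
    # ties also force the asymptotic path
    res = mann_whitney(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 5.0]))
    assert res.method == "asymptotic"


def test_mw_identical_samples():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert mann_whitney(a, a.copy()).p_raw == pytest.approx(1.0)


def test_mw_separated_samples_minimal_p():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = a + 100.0
    res = mann_whitney(a, b)
    # the most extreme of C(10,5) = 252 tables: two-sided p = 2/252
    assert res.p_raw == pytest.approx(2.0 / 252.0, abs=1e-12)


def test_mw_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney(np.array([]), np.array([1.0]))


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# --------------------------------------------------------------------------

def test_kw_h_matches_bruteforce(rng):
    groups = [rng.normal(size=8), rng.normal(size=6) + 1, rng.normal(size=7)]
    res = kruskal_wallis_dunn(_long_table({"a": groups[0], "b": groups[1], "c": groups[2]}))
    assert res.statistic == pytest.approx(_oracles.kruskal_h_bruteforce(groups), abs=1e-9)


def test_kw_h_matches_bruteforce_with_ties(rng):
    groups = [
        np.round(rng.normal(size=10), 0),
        np.round(rng.normal(size=10) + 0.5, 0),
    ]
    res = kruskal_wallis_dunn(_long_table({"a": groups[0], "b": groups[1]}))
    assert res.statistic == pytest.approx(_oracles.kruskal_h_bruteforce(groups), abs=1e-9)


def test_kw_all_identical_values():
    res = kruskal_wallis_dunn(_long_table({"a": np.ones(5), "b": np.ones(5)}))
    assert res.statistic == 0.0
    assert res.p_raw == 1.0


def test_kw_separated_groups_significant():
    res = kruskal_wallis_dunn(
        _long_table({"a": np.arange(10.0), "b": np.arange(10.0) + 100, "c": np.arange(10.0) + 200})
    )
    assert res.p_raw < 1e-4
    assert all(c.p_adj < 0.05 for c in res.pairwise)
    extreme = next(c for c in res.pairwise if {c.a, c.b} == {"a", "c"})
    assert extreme.p_adj < 0.01


def test_dunn_adjustment_properties(rng):
    res = kruskal_wallis_dunn(
        _long_table({"a": rng.normal(size=8), "b": rng.normal(size=8) + 1, "c": rng.normal(size=8)})
    )
    assert len(res.pairwise) == 3
    for c in res.pairwise:
        assert c.p_adj >= c.p_raw - 1e-15
        assert c.p_adj <= 1.0
        assert c.p_adj == pytest.approx(min(1.0, 3 * c.p_raw), abs=1e-12)


def test_dunn_restricted_family():
    rng = np.random.default_rng(3)
    table = _long_table(
        {"ctrl": rng.normal(size=8), "kd1": rng.normal(size=8), "kd2": rng.normal(size=8)}
    )
    res = kruskal_wallis_dunn(table, comparisons=[("ctrl", "kd1"), ("ctrl", "kd2")])
    assert len(res.pairwise) == 2
    assert all(c.p_adj == pytest.approx(min(1.0, 2 * c.p_raw), abs=1e-12) for c in res.pairwise)


def test_kw_validation():
    with pytest.raises(ValueError):
        kruskal_wallis_dunn(_long_table({"a": np.ones(5)}))
    with pytest.raises(ValueError):
        kruskal_wallis_dunn(_long_table({"a": np.ones(5), "b": np.ones(1)}))


# --------------------------------------------------------------------------
# one-sample t with Bonferroni
# --------------------------------------------------------------------------

def test_one_sample_t_hand_check(rng):
    v = np.array([0.3, 0.5, 0.1, 0.7, 0.4])
    res = one_sample_t_bonferroni({"gamma": v, "alpha_prime": v - 0.4})
    t_expected = v.mean() / (v.std(ddof=1) / math.sqrt(5))
    c = {p.a: p for p in res.pairwise}
    assert c["gamma"].statistic == pytest.approx(t_expected, abs=1e-12)
    assert c["gamma"].p_adj == pytest.approx(min(1.0, 2 * c["gamma"].p_raw), abs=1e-12)
    t_ref, p_ref = sps.ttest_1samp(v, 0.0)
    assert c["gamma"].p_raw == pytest.approx(p_ref, abs=1e-12)


def test_one_sample_t_symmetric_values_p_one():
    res = one_sample_t_bonferroni({"r": np.array([-2.0, -1.0, 1.0, 2.0])})
    assert res.pairwise[0].p_raw == pytest.approx(1.0)


def test_one_sample_t_zero_variance_flagged():
    res = one_sample_t_bonferroni({"r": np.full(4, 0.5), "s": np.zeros(4)})
    c = {p.a: p for p in res.pairwise}
    assert c["r"].p_raw == 0.0  # constant nonzero mean: trivially different
    assert c["s"].p_raw == 1.0  # constant at mu
    assert any("zero variance" in n for n in res.notes)


def test_one_sample_t_explicit_family_size():
    v = np.random.default_rng(1).normal(size=6) + 1
    res = one_sample_t_bonferroni({"r": v}, m=5)
    assert res.pairwise[0].p_adj == pytest.approx(min(1.0, 5 * res.pairwise[0].p_raw), abs=1e-12)


# --------------------------------------------------------------------------
# mixed-design RM ANOVA + Holm-Sidak
# --------------------------------------------------------------------------

def _mixed_table(rng, n_per=6, group_effect=0.0, inter_effect=0.0):
    rows = []
    for g, gname in enumerate(("ctrl", "kd")):
        for s in range(n_per):
            base = rng.normal(0, 1)
            for w, wname in enumerate(("pre", "post")):
                rows.append(
                    dict(
                        unit_id=f"{gname}{s}",
                        group=gname,
                        within=wname,
                        value=base + group_effect * g + inter_effect * g * w + rng.normal(0, 0.5),
                    )
                )
    return pd.DataFrame(rows)


def test_rm_anova_matches_ss_oracle(rng):
    df = _mixed_table(rng, inter_effect=0.8)
    res = rm_anova_holm_sidak(df)
    oracle = _oracles.mixed_anova_ss_bruteforce(df, "value", "within", "group", "unit_id")
    aov = res.anova.set_index("Source")
    assert aov.loc["group", "SS"] == pytest.approx(oracle["ss_group"], abs=1e-9)
    assert aov.loc["within", "SS"] == pytest.approx(oracle["ss_within"], abs=1e-9)
    assert aov.loc["Interaction", "SS"] == pytest.approx(oracle["ss_interaction"], abs=1e-9)
    assert aov.loc["group", "F"] == pytest.approx(oracle["f_group"], abs=1e-9)
    assert aov.loc["within", "F"] == pytest.approx(oracle["f_within"], abs=1e-9)
    assert res.statistic == pytest.approx(oracle["f_interaction"], abs=1e-9)


def test_rm_anova_detects_interaction(rng):
    df = _mixed_table(rng, n_per=12, inter_effect=2.0)
    res = rm_anova_holm_sidak(df)
    assert res.p_raw < 0.001
    # one contrast per within level, labelled with the level
    labels = [f"{p.a} {p.b}" for p in res.pairwise]
    assert any("post" in lab for lab in labels)
    assert any("pre" in lab for lab in labels)


def test_rm_anova_drops_incomplete_units(rng):
    df = _mixed_table(rng)
    df = df[~((df["unit_id"] == "ctrl0") & (df["within"] == "post"))]
    res = rm_anova_holm_sidak(df)
    assert res.n["units"] == 11
    assert any("ctrl0" in n for n in res.notes)


def test_rm_anova_holm_sidak_adjustment_formula(rng):
    df = _mixed_table(rng, inter_effect=1.0)
    res = rm_anova_holm_sidak(df)
    raws = sorted(p.p_raw for p in res.pairwise)
    m = len(raws)
    # step-down Holm-Sidak with monotonicity enforcement
    adj, prev = [], 0.0
    for i, p in enumerate(raws):
        a = 1.0 - (1.0 - p) ** (m - i)
        prev = max(prev, a)
        adj.append(prev)
    got = sorted(p.p_adj for p in res.pairwise)
    assert np.allclose(got, adj, atol=1e-12)


# --------------------------------------------------------------------------
# power
# --------------------------------------------------------------------------

def _normal_shift_sampler(delta):
    def sampler(rng, n):
        return rng.normal(0, 1, n), rng.normal(delta, 1, n)

    return sampler


def test_power_monotone_in_effect_size():
    p0 = power_two_sample(_normal_shift_sampler(0.0), 8, n_sims=300, seed=1).power
    p1 = power_two_sample(_normal_shift_sampler(1.0), 8, n_sims=300, seed=1).power
    p2 = power_two_sample(_normal_shift_sampler(3.0), 8, n_sims=300, seed=1).power
    assert p0 < p1 < p2
    assert p2 > 0.95


def test_power_null_near_alpha():
    res = power_two_sample(_normal_shift_sampler(0.0), 8, alpha=0.05, n_sims=1000, seed=2)
    assert res.ci_low < 0.05 < res.ci_high + 0.02  # CI roughly brackets alpha
    assert 0.02 < res.power < 0.09


def test_power_deterministic_and_validated():
    a = power_two_sample(_normal_shift_sampler(0.8), 6, n_sims=200, seed=5)
    b = power_two_sample(_normal_shift_sampler(0.8), 6, n_sims=200, seed=5)
    assert a.power == b.power
    with pytest.raises(ValueError):
        power_two_sample(_normal_shift_sampler(0.8), 6, n_sims=50, seed=5)
    with pytest.raises(ValueError):
        power_two_sample(_normal_shift_sampler(0.8), 6, n_sims=200, seed=5, test="bogus")


# --------------------------------------------------------------------------
# ddCt
# --------------------------------------------------------------------------

def test_ddct_calibrator_fold_is_one():
    ct = pd.DataFrame(
        dict(
            sample=["control"] * 3 + ["kd"] * 3,
            replicate=[0, 1, 2] * 2,
            target_ct=[25.0, 25.2, 24.8, 26.0, 26.2, 25.8],
            reference_ct=[20.0, 20.0, 20.0, 20.0, 20.0, 20.0],
        )
    )
    out = ddct_fold_change(ct, calibrator_sample="control")
    got = dict(zip(out["sample"], out["fold_change"]))
    assert got["control"] == pytest.approx(1.0, abs=1e-12)
    # kd is one cycle later -> half the expression
    assert got["kd"] == pytest.approx(0.5, abs=1e-12)


def test_ddct_missing_reference_dropped():
    ct = pd.DataFrame(
        dict(
            sample=["control", "control", "kd", "bad"],
            replicate=[0, 1, 0, 0],
            target_ct=[25.0, 25.0, 26.0, 30.0],
            reference_ct=[20.0, 20.0, 20.0, np.nan],
        )
    )
    out = ddct_fold_change(ct, calibrator_sample="control")
    assert "bad" not in set(out["sample"])
    assert out.attrs["dropped_samples"] == ["bad"]


def test_ddct_missing_calibrator_raises():
    ct = pd.DataFrame(
        dict(sample=["kd"], replicate=[0], target_ct=[26.0], reference_ct=[20.0])
    )
    with pytest.raises(ValueError):
        ddct_fold_change(ct, calibrator_sample="control")


@pytest.fixture
def rng():
    return np.random.default_rng(31337)
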