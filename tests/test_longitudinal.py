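"""Paired tests, mixed models, FDR and correlation of changes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gratiokit.longitudinal import (
    change_correlation,
    fdr_adjust,
    fit_lmm,
    marginal_r2,
    paired_t,
    subgroup_welch,
)


def _diffs_with_moments(mean, sd, n, rng):
    """A difference vector with exactly the requested sample mean and SD."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


# ---- paired t ------------------------------------------------------------


def test_paired_t_from_summary_moments(rng):
    d = _diffs_with_moments(0.47, 1.05, 62, rng)
    res = paired_t(np.zeros(62), d)
    assert round(res.t, 2) == 3.52
    assert res.df == 61
    assert res.p < 0.001


def test_paired_t_symmetric_differences():
    res = paired_t(np.zeros(3), np.array([-1.0, 0.0, 1.0]))
    assert res.t == 0.0
    assert res.p == 1.0


def test_paired_t_matches_closed_form(rng):
    v1 = rng.normal(size=30)
    v2 = rng.normal(size=30)
    res = paired_t(v1, v2)
    d = v2 - v1
    t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(30))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), 29)
    assert res.t == pytest.approx(t_oracle, abs=1e-12)
    assert res.p == pytest.approx(p_oracle, abs=1e-12)


def test_paired_t_zero_variance_flagged():
    res = paired_t(np.zeros(4), np.full(4, 0.5))
    assert np.isinf(res.t) and res.t > 0


# ---- FDR -----------------------------------------------------------------


def _bh_by_hand(p):
    """Step-up BH with monotonicity, spelled out."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    q_sorted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_fdr_single_p_unchanged():
    np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])


def test_fdr_hand_example():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_fdr_monotone_and_bounded(rng):
    p = rng.random(10)
    q = fdr_adjust(p)
    assert np.all(q <= 1.0) and np.all(q >= p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_fdr_matches_hand_enumeration_over_permutations():
    base = [0.001, 0.011, 0.034, 0.04, 0.2, 0.89]
    for perm in itertools.permutations(base):
        np.testing.assert_allclose(fdr_adjust(list(perm)), _bh_by_hand(perm), atol=1e-14)


def test_fdr_rejects_invalid_p():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])


# ---- correlations / subgroup tests ---------------------------------------


def test_proportional_changes_have_unit_r2():
    a = np.array([0.1, -0.2, 0.4, 0.3])
    r, r2, _ = change_correlation(a, 3.0 * a)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_correlation_matches_direct_formula():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 4.0, 5.0, 9.0])
    r, r2, p = change_correlation(a, b)
    ca, cb = a - a.mean(), b - b.mean()
    r_oracle = (ca @ cb) / np.sqrt((ca @ ca) * (cb @ cb))
    t_oracle = r_oracle * np.sqrt(2 / (1 - r_oracle**2))
    p_oracle = 2 * stats.t.sf(abs(t_oracle), 2)
    assert r == pytest.approx(r_oracle, abs=1e-12)
    assert p == pytest.approx(p_oracle, abs=1e-9)


def test_independent_changes_nearly_uncorrelated(rng):
    r, _, _ = change_correlation(rng.normal(size=10_000), rng.normal(size=10_000))
    assert abs(r) < 0.03


def test_correlation_rejects_degenerate_input():
    with pytest.raises(ValueError):
        change_correlation(np.ones(5), np.arange(5.0))


def test_welch_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    t, df, p = subgroup_welch(x, labels)
    assert t == 0.0
    assert df == pytest.approx(4.0)  # equal variance, equal n -> 2n-2


def test_welch_matches_formula(rng):
    x = rng.normal(0, 1, 12)
    y = rng.normal(0.8, 2, 9)
    t, df, p = subgroup_welch(
        np.concatenate([x, y]), np.array(["no"] * 12 + ["yes"] * 9)
    )
    vx, vy = x.var(ddof=1) / 12, y.var(ddof=1) / 9
    t_oracle = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df_oracle = (vx + vy) ** 2 / (vx**2 / 11 + vy**2 / 8)
    assert t == pytest.approx(t_oracle, abs=1e-12)
    assert df == pytest.approx(df_oracle, abs=1e-9)


def test_welch_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        subgroup_welch(np.arange(4.0), np.array(["a", "a", "a", "b"]))


# ---- mixed models --------------------------------------------------------


def test_marginal_r2_arithmetic():
    assert marginal_r2(1.0, 1.0, 2.0) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        marginal_r2(0.0, 0.0, 0.0)


def _simulate_lmm_data(rng, n_subjects=40, beta_time=0.005, sd_subject=0.02, sd_resid=0.01):
    rows = []
    for i in range(n_subjects):
        intercept = 1.0 + rng.normal(0, sd_subject)
        age = rng.uniform(20, 60)
        sex = rng.choice(["F", "M"])
        dmt = bool(rng.random() < 0.5)
        ll = rng.uniform(0, 2)
        for t in (0.0, 1.0):
            rows.append(
                {
                    "subject": f"S{i}",
                    "time": t,
                    "age": age,
                    "sex": sex,
                    "dmt": dmt,
                    "lesion_load": ll,
                    "value": intercept + beta_time * t + rng.normal(0, sd_resid),
                }
            )
    return pd.DataFrame(rows)


def test_lmm_time_effect_ci_coverage(rng):
    """beta_time's 95% CI covers the simulated effect in >=90% of replicates."""
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        data = _simulate_lmm_data(rng)
        res = fit_lmm(data)
        assert res.converged
        lo, hi = res.beta_time - 1.96 * res.se, res.beta_time + 1.96 * res.se
        hits += lo <= 0.005 <= hi
    assert hits / n_rep >= 0.90


def test_lmm_null_effect_mostly_insignificant(rng):
    quiet = 0
    n_rep = 20
    for _ in range(n_rep):
        data = _simulate_lmm_data(rng, beta_time=0.0)
        res = fit_lmm(data)
        quiet += abs(res.t) < 2.0
    assert quiet / n_rep >= 0.8


def test_lmm_variance_components_reasonable(rng):
    data = _simulate_lmm_data(rng, n_subjects=120, sd_subject=0.05, sd_resid=0.02)
    res = fit_lmm(data)
    assert res.sigma2_random == pytest.approx(0.05**2, rel=0.5)
    assert res.sigma2_resid == pytest.approx(0.02**2, rel=0.5)
    assert 0.0 <= res.marginal_r2 <= 1.0


def test_lmm_missing_columns_rejected():
    with pytest.raises(ValueError):
        fit_lmm(pd.DataFrame({"value": [1.0], "time": [0.0], "subject": ["a"]}))
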