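"""Mann-Whitney U (exact vs enumeration), Pearson r, condition comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stormquant.stats import (
    compare_conditions,
    correlate_nuclear_cytosolic,
    mann_whitney_u,
    pearson_r,
)


def enumeration_mwu(x, y):
    """Exhaustive two-sided exact test: U of x and P(|U - nm/2| >= |u - nm/2|)
    over all C(n+m, n) group assignments of the pooled values."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = x + y
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    center = n * m / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


def test_textbook_example_u0_p01():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.u_statistic == 0
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.method == "exact"


def test_exact_path_matches_enumeration_small_samples(rng):
    for n in range(1, 6):
        for m in range(1, 11 - n):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            res = mann_whitney_u(x, y)
            u_ref, p_ref = enumeration_mwu(x, y)
            assert res.u_statistic == pytest.approx(u_ref, abs=1e-12)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)


def test_identical_samples_p_near_one(rng):
    x = rng.normal(size=30)
    res = mann_whitney_u(x, x)
    assert res.p_value > 0.9


def test_asymptotic_switch_on_large_or_tied():
    big = mann_whitney_u(np.arange(25, dtype=float), np.arange(25, dtype=float) + 0.5)
    assert big.method == "asymptotic"
    tied = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0])
    assert tied.method == "asymptotic"


@given(st.integers(0, 2**31 - 1))
def test_u_statistics_sum_to_nm(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=8)
    y = rng.normal(size=6)
    assert (
        mann_whitney_u(x, y).u_statistic + mann_whitney_u(y, x).u_statistic
        == 8 * 6
    )


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# --- Pearson ---------------------------------------------------------------


def test_pearson_perfect_lines(rng):
    x = rng.normal(size=20)
    assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson_r(x, -x).r == pytest.approx(-1.0)


def test_pearson_five_point_table_hand_computed():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 4.0, 3.0, 5.0]
    # direct formula: r = cov(x, y) / (sd_x sd_y)
    xm, ym = np.mean(x), np.mean(y)
    r_hand = float(
        np.sum((np.array(x) - xm) * (np.array(y) - ym))
        / math.sqrt(np.sum((np.array(x) - xm) ** 2) * np.sum((np.array(y) - ym) ** 2))
    )
    assert pearson_r(x, y).r == pytest.approx(r_hand, abs=1e-12)
    assert r_hand == pytest.approx(0.8, abs=1e-12)


def test_pearson_affine_invariance(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = pearson_r(x, y).r
    assert pearson_r(3 * x + 7, y).r == pytest.approx(base, abs=1e-12)
    assert pearson_r(-2 * x, y).r == pytest.approx(-base, abs=1e-12)


def test_pearson_rejects_constant():
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --- condition comparisons -------------------------------------------------


def _records(values_a, values_b, metric="mean_fwhm_nm"):
    rows = [{"condition": "a", metric: v} for v in values_a]
    rows += [{"condition": "b", metric: v} for v in values_b]
    return pd.DataFrame(rows)


def test_identical_arms_p_near_one(rng):
    vals = rng.normal(90, 5, 20)
    res, summary = compare_conditions(_records(vals, vals), "mean_fwhm_nm")
    assert res.p_value > 0.9
    assert (summary["n"] == 20).all()


def test_separated_arms_significant_with_direction(rng):
    a = rng.normal(90, 8, 30)
    b = rng.normal(45, 6, 30)
    res, _ = compare_conditions(_records(a, b), "mean_fwhm_nm")
    assert res.p_value < 1e-3
    assert res.median_x > res.median_y


def test_nan_cells_excluded_and_all_nan_arm_errors(rng):
    df = _records(rng.normal(90, 5, 10), [np.nan] * 10)
    with pytest.raises(ValueError, match="no usable cells"):
        compare_conditions(df, "mean_fwhm_nm")
    df2 = _records(list(rng.normal(90, 5, 10)) + [np.nan], rng.normal(45, 5, 10))
    res, summary = compare_conditions(df2, "mean_fwhm_nm")
    assert summary.loc[summary.condition == "a", "n"].iloc[0] == 10


def test_correlation_signs_follow_configured_coupling(rng):
    n = 100
    z = rng.normal(size=n)
    fwhm = 60 + 8 * z
    cyto_count = np.round(12 * (1 + 0.35 * (-0.6 * z + 0.8 * rng.normal(size=n))))
    cyto_size = 40 + 6 * (0.5 * z + 0.86 * rng.normal(size=n))
    df = pd.DataFrame(
        {
            "mean_fwhm_nm": fwhm,
            "mean_cyto_fwhm_nm": cyto_size,
            "n_cytosolic_clusters": cyto_count,
        }
    )
    r_size, r_count = correlate_nuclear_cytosolic(df)
    assert r_size.r > 0
    assert r_count.r < 0


def test_correlation_requires_enough_cells():
    df = pd.DataFrame(
        {"mean_fwhm_nm": [1.0, 2.0], "mean_cyto_fwhm_nm": [1.0, 2.0], "n_cytosolic_clusters": [1, 2]}
    )
    with pytest.raises(ValueError):
        correlate_nuclear_cytosolic(df)
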