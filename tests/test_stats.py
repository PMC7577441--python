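"""Agreement and power statistics against hand oracles and reference packages."""

import numpy as np
import pandas as pd
import pytest

from femhu import (PowerSpec, RaterTable, bland_altman, icc_absolute_single,
                   limits_of_agreement, paired_t, power_paired_t,
                   sample_size_paired_t, simulate_rater_table, welch_t)
from femhu.stats import icc_category


def icc_a1_oracle(x):
    """Explicit sum-of-squares arithmetic for ICC(A,1), written independently."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_identical_raters_give_icc_one():
    col = np.array([1.0, 2.0, 5.0, 9.0])
    res = icc_absolute_single(RaterTable(np.column_stack([col, col])))
    assert res.icc == 1.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)
    assert res.category == "excellent"


def test_icc_hand_table_matches_sum_of_squares_oracle():
    x = np.array([[9.0, 2.0], [4.0, 5.0], [7.0, 8.0], [6.0, 3.0], [10.0, 7.0]])
    res = icc_absolute_single(RaterTable(x))
    assert res.icc == pytest.approx(icc_a1_oracle(x), abs=1e-12)


def test_icc_matches_oracle_on_random_tables(rng):
    for _ in range(100):
        n = int(rng.integers(3, 12))
        k = int(rng.integers(2, 5))
        x = rng.normal(size=(n, k)) * 5 + rng.normal(size=(n, 1)) * 3
        res = icc_absolute_single(RaterTable(x))
        assert res.icc == pytest.approx(icc_a1_oracle(x), abs=1e-10)


def test_icc_and_ci_match_pingouin():
    """Independent reference: pingouin's ICC2 (single-measure absolute agreement)."""
    import pingouin as pg

    rng = np.random.default_rng(21)
    n, k = 30, 3
    x = rng.normal(size=(n, 1)) * 4 + rng.normal(size=(n, k)) + np.array([0.0, 0.5, -0.3])
    res = icc_absolute_single(RaterTable(x))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": x.ravel(),
    })
    ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score").set_index("Type").loc["ICC(A,1)"]
    assert res.icc == pytest.approx(float(ref["ICC"]), abs=1e-9)
    # pingouin prints the CI rounded to 2 decimals
    assert res.ci_low == pytest.approx(ref["CI95"][0], abs=6e-3)
    assert res.ci_high == pytest.approx(ref["CI95"][1], abs=6e-3)


def test_icc_invariant_under_shift_and_positive_scaling(rng):
    x = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1)) * 3
    base = icc_absolute_single(RaterTable(x)).icc
    assert icc_absolute_single(RaterTable(x + 100.0)).icc == pytest.approx(base, abs=1e-10)
    assert icc_absolute_single(RaterTable(x * 3.5)).icc == pytest.approx(base, abs=1e-10)


def test_icc_degenerate_table_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        icc_absolute_single(RaterTable(np.full((4, 2), 7.0)))


def test_icc_parameter_recovery_at_large_n():
    """Averaged over replicate tables, the ICC(A,1) estimate recovers the
    analytic variance-ratio 100/102 within ±0.01."""
    estimates = []
    for rep in range(20):
        table, analytic = simulate_rater_table(
            2000, 2, subject_sd=10.0, rater_bias_sds=1.0, residual_sd=1.0,
            seed=1000 + rep)
        estimates.append(icc_absolute_single(table).icc)
    assert analytic == pytest.approx(100.0 / 102.0)
    assert np.mean(estimates) == pytest.approx(analytic, abs=0.01)


@pytest.mark.parametrize("icc,expected", [
    (0.3, "poor"), (0.6, "moderate"), (0.85, "good"), (0.95, "excellent"),
    (0.75, "moderate"), (0.90, "good"), (0.901, "excellent"),
])
def test_icc_reliability_categories(icc, expected):
    assert icc_category(icc) == expected


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def test_identical_pairs_have_zero_width_loa():
    a = np.array([3.0, 4.0, 5.0])
    res = bland_altman(a, a)
    assert (res.mean_diff, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)


@pytest.mark.parametrize("mean_diff,sd_diff,expected", [
    (-2.24, 14.16, (-30.0, 25.5)),  # mean HU, pre − post
    (-1.13, 1.26, (-3.6, 1.3)),     # HUHA_fat (%), pre − post
    (-2.23, 2.19, (-6.5, 2.1)),     # HUHA_dense-bone (%), pre − post
])
def test_printed_summary_loa(mean_diff, sd_diff, expected):
    lo, hi = limits_of_agreement(mean_diff, sd_diff)
    assert (round(lo, 1), round(hi, 1)) == expected


def test_bland_altman_formulas_and_coordinates(rng):
    a, b = rng.normal(size=50), rng.normal(size=50)
    res = bland_altman(a, b)
    d = a - b
    assert res.mean_diff == pytest.approx(d.mean())
    assert res.sd_diff == pytest.approx(d.std(ddof=1))
    assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
    assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
    assert np.allclose(res.coordinates[:, 0], (a + b) / 2)
    assert np.allclose(res.coordinates[:, 1], d)
    assert res.orientation == "first - second"


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError):
        bland_altman([1.0], [2.0])


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def test_paired_t_all_equal_pairs():
    a = np.array([1.0, 2.0, 3.0])
    res = paired_t(a, a)
    assert (res.t, res.p) == (0.0, 1.0)


def test_paired_t_hand_arithmetic():
    second = np.zeros(4)
    first = np.array([1.0, 2.0, 3.0, 4.0])
    res = paired_t(first, second)
    assert res.mean_diff == pytest.approx(2.5)
    assert res.sd_diff == pytest.approx(1.2910, abs=5e-5)
    assert res.t == pytest.approx(3.873, abs=5e-4)
    assert res.df == 3


def test_paired_t_antisymmetric_differences_give_zero_t():
    diffs = np.array([-3.0, -1.0, 1.0, 3.0])
    res = paired_t(diffs, np.zeros_like(diffs))
    assert res.t == 0.0


def test_paired_t_matches_scipy():
    from scipy import stats as sps

    rng = np.random.default_rng(3)
    a, b = rng.normal(size=25), rng.normal(size=25)
    res = paired_t(a, b)
    ref = sps.ttest_rel(a, b)
    assert res.t == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
    lo, hi = ref.confidence_interval()
    assert (res.ci_low, res.ci_high) == (pytest.approx(lo), pytest.approx(hi))


def test_paired_t_constant_offset_recovered_exactly(rng):
    x = rng.normal(size=30)
    jitter = np.tile([0.5, -0.5], 15)  # exactly representable, sums to zero
    res = paired_t(x, x + 4.25 + jitter)
    assert res.mean_diff == -4.25


def test_paired_t_constant_difference_is_degenerate():
    x = np.arange(5.0)
    with pytest.raises(ValueError, match="degenerate"):
        paired_t(x, x + 4.25)


def test_paired_t_degenerate_nonzero_constant_difference():
    with pytest.raises(ValueError, match="degenerate"):
        paired_t(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


def test_welch_identical_groups():
    g = np.array([1.0, 2.0, 3.0])
    assert welch_t(g, g.copy()).t == 0.0


def test_welch_equal_variance_df_limit():
    a = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    b = a + 0.5
    res = welch_t(a, b)
    assert res.df == pytest.approx(len(a) + len(b) - 2, abs=1e-6)


def test_welch_matches_explicit_formula_and_scipy():
    from scipy import stats as sps

    a = np.array([12.1, 9.8, 11.4, 10.2, 13.0])
    b = np.array([8.2, 9.9, 7.7, 10.5, 8.8])
    res = welch_t(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / 5 + vb / 5
    t_expected = (a.mean() - b.mean()) / np.sqrt(se2)
    df_expected = se2 ** 2 / ((va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4)
    assert res.t == pytest.approx(t_expected, abs=1e-12)
    assert res.df == pytest.approx(df_expected, abs=1e-12)
    ref = sps.ttest_ind(a, b, equal_var=False)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_welch_degenerate_variances_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        welch_t(np.array([1.0, 1.0]), np.array([2.0, 2.0]))


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

def test_two_tailed_power_at_study_design():
    power = power_paired_t(PowerSpec(effect_size=0.5, alpha=0.05, tails=2), 50)
    assert power >= 0.93


def test_one_tailed_sample_size_for_95_power():
    n = sample_size_paired_t(PowerSpec(effect_size=0.5, alpha=0.05, tails=1), 0.95)
    assert n == 45


def test_power_matches_statsmodels():
    from statsmodels.stats.power import TTestPower

    spec = PowerSpec(effect_size=0.5, alpha=0.05, tails=2)
    ref = TTestPower().power(effect_size=0.5, nobs=50, alpha=0.05,
                             alternative="two-sided")
    assert power_paired_t(spec, 50) == pytest.approx(ref, abs=1e-8)
    spec1 = PowerSpec(effect_size=0.5, alpha=0.05, tails=1)
    ref1 = TTestPower().power(effect_size=0.5, nobs=45, alpha=0.05,
                              alternative="larger")
    assert power_paired_t(spec1, 45) == pytest.approx(ref1, abs=1e-8)


def test_huge_effect_size_saturates_power():
    assert power_paired_t(PowerSpec(effect_size=10.0), 5) > 0.999
    # at fixed n the power is monotone toward 1 as d grows
    assert (power_paired_t(PowerSpec(effect_size=100.0), 2)
            > power_paired_t(PowerSpec(effect_size=10.0), 2))


def test_power_monotone_in_n_and_d_and_tails():
    spec = PowerSpec(effect_size=0.5, alpha=0.05, tails=2)
    powers = [power_paired_t(spec, n) for n in range(2, 80)]
    assert all(b >= a for a, b in zip(powers, powers[1:]))
    assert (power_paired_t(PowerSpec(effect_size=0.8), 30)
            > power_paired_t(PowerSpec(effect_size=0.5), 30))
    assert (power_paired_t(PowerSpec(effect_size=0.5, tails=2), 30)
            <= power_paired_t(PowerSpec(effect_size=0.5, tails=1), 30))


def test_sample_size_minimality_contract():
    spec = PowerSpec(effect_size=0.4, alpha=0.05, tails=2)
    n = sample_size_paired_t(spec, 0.9)
    assert power_paired_t(spec, n) >= 0.9
    assert power_paired_t(spec, n - 1) < 0.9


def test_sample_size_terminates_for_extreme_power():
    n = sample_size_paired_t(PowerSpec(effect_size=0.5), 0.999999)
    assert np.isfinite(n) and n > 2
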