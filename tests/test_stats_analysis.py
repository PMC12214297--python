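"""Gated statistical tests, ICC, chi-square, and the report formatter."""

import numpy as np
import pandas as pd
import pytest

from ossimetry import stats_analysis as sa


# -- ICC --------------------------------------------------------------------

def test_icc_identical_replicates_is_exactly_one():
    subjects = np.arange(10, dtype=float)
    mat = np.stack([subjects] * 3, axis=1)
    res = sa.icc_consistency(mat)
    assert res.icc_value == 1.0
    assert res.consistency_band == "high"


def test_icc_pure_noise_replicates_near_zero():
    rng = np.random.default_rng(0)
    mat = np.full((50, 3), 5.0) + rng.normal(0, 1, (50, 3))
    res = sa.icc_consistency(mat)
    assert res.icc_value < 0.2


def test_icc_recovers_variance_ratio():
    """sigma_b=1, sigma_e=0.5 => ICC = 1/(1+0.25) = 0.8 within 0.05."""
    rng = np.random.default_rng(42)
    n, k = 200, 3
    subject = rng.normal(0, 1.0, n)[:, None]
    mat = subject + rng.normal(0, 0.5, (n, k))
    res = sa.icc_consistency(mat)
    assert res.icc_value == pytest.approx(0.8, abs=0.05)
    assert res.model_tag.startswith("ICC(3,1)")


def test_icc_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    mat = rng.normal(0, 1, (30, 3)) + rng.normal(0, 1, 30)[:, None]
    mine = sa.icc_consistency(mat).icc_value
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(30), 3),
        "rater": np.tile(np.arange(3), 30),
        "value": mat.ravel(),
    })
    table = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                     ratings="value").set_index("Type")
    icc3 = table.loc["ICC(C,1)", "ICC"]  # two-way mixed, consistency, single
    assert mine == pytest.approx(float(icc3), abs=1e-9)


def test_icc_input_validation():
    with pytest.raises(ValueError):
        sa.icc_consistency(np.ones((1, 3)))
    with pytest.raises(ValueError):
        sa.icc_consistency(np.array([[1.0, np.nan], [2.0, 2.0]]))


# -- paired comparison ------------------------------------------------------

def test_paired_identical_vectors_short_circuit():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = sa.paired_comparison(x, x)
    assert res.p_value == 1.0
    assert res.test_name == "exact-equality"


def test_paired_normal_differences_choose_t():
    rng = np.random.default_rng(1)
    x = rng.normal(10, 1, 47)
    y = x + rng.normal(0, 0.5, 47)
    res = sa.paired_comparison(x, y)
    assert res.test_name == "paired t"
    assert res.normality_used


def test_paired_cauchy_differences_choose_wilcoxon():
    rng = np.random.default_rng(2)
    chosen = []
    for _ in range(200):
        x = rng.normal(0, 1, 47)
        y = x + rng.standard_cauchy(47)
        chosen.append(sa.paired_comparison(x, y).test_name)
    frac = np.mean([c == "Wilcoxon signed-rank" for c in chosen])
    assert frac >= 0.95


def test_paired_length_mismatch_rejected():
    with pytest.raises(ValueError):
        sa.paired_comparison([1, 2, 3], [1, 2])


# -- group comparisons ------------------------------------------------------

def test_group_identical_samples_p_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = sa.group_comparison(x, x.copy())
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_group_shifted_normals_rejected_null():
    rng = np.random.default_rng(0)
    res = sa.group_comparison(rng.normal(0, 1, 100), rng.normal(1, 1, 100))
    assert res.p_value < 1e-6


def test_group_too_small_rejected():
    with pytest.raises(ValueError):
        sa.group_comparison([1.0, 2.0], [1.0, 2.0, 3.0])


def test_multi_group_identical_groups():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    res = sa.multi_group_comparison([g, g.copy(), g.copy()])
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_multi_group_shifted_third_group_uses_anova():
    rng = np.random.default_rng(5)
    groups = [rng.normal(0, 1, 80), rng.normal(0, 1, 80), rng.normal(1, 1, 80)]
    res = sa.multi_group_comparison(groups)
    assert res.p_value < 1e-4
    assert res.test_name == "one-way ANOVA"


def test_multi_group_needs_three_groups():
    with pytest.raises(ValueError):
        sa.multi_group_comparison([[1, 2, 3], [4, 5, 6]])


def test_rank_tests_invariant_to_monotone_transform():
    rng = np.random.default_rng(9)
    x = rng.standard_cauchy(40)
    y = rng.standard_cauchy(40) + 1.0
    r1 = sa.group_comparison(x, y)
    r2 = sa.group_comparison(np.exp(x / 10), np.exp(y / 10))
    if r1.test_name == r2.test_name == "Mann-Whitney U":
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-12)


# -- chi square -------------------------------------------------------------

def test_chi_square_sex_distribution_example():
    """75 vs 65 against uniform: chi2 = 0.714, p = 0.398."""
    res = sa.chi_square_gof([75, 65])
    assert res.statistic == pytest.approx(0.7143, abs=1e-4)
    assert res.p_value == pytest.approx(0.398, abs=5e-4)


def test_chi_square_balanced_counts():
    res = sa.chi_square_gof([50, 50])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_chi_square_extreme_counts():
    res = sa.chi_square_gof([10, 0])
    assert res.statistic == pytest.approx(10.0, abs=1e-12)
    assert res.p_value == pytest.approx(0.001565, abs=1e-5)


def test_chi_square_all_zero_rejected():
    with pytest.raises(ValueError):
        sa.chi_square_gof([0, 0, 0])


# -- formatting / summary table ---------------------------------------------

def test_percent_formatting_demographics():
    assert sa.format_percent(75, 140) == "53.6"
    assert sa.format_percent(130, 226) == "57.5"
    assert sa.format_percent(96, 226) == "42.5"


def test_mean_sd_formatting():
    vals = [7.0, 8.0, 9.0]
    assert sa.format_mean_sd(vals) == "8.00 ± 1.00"


def _toy_table(rng, n_ears=20, grouping=True):
    rows = []
    for ear in range(n_ears):
        sex = "F" if ear % 2 else "M"
        for method in ("manual", "automated"):
            for rep in range(3):
                rows.append(dict(ear_id=ear, sex=sex, parameter="height",
                                 method=method, replicate=rep,
                                 value=7.9 + 0.5 * (sex == "M") + rng.normal(0, 0.2)))
    return pd.DataFrame(rows)


def test_summary_table_cells_match_recomputation():
    rng = np.random.default_rng(0)
    table = _toy_table(rng)
    out = sa.summary_table(table, grouping="sex")
    merged = table.groupby(["ear_id", "sex"])["value"].mean().reset_index()
    for sex in ("F", "M"):
        vals = merged.loc[merged.sex == sex, "value"]
        assert out.iloc[0][sex] == sa.format_mean_sd(vals)
    assert 0.0 <= out.iloc[0]["p_value"] <= 1.0


def test_summary_table_method_agreement_with_icc():
    rng = np.random.default_rng(1)
    out = sa.summary_table(_toy_table(rng), compare_methods=True)
    assert {"manual", "automated", "icc", "p_value"} <= set(out.columns)
    assert -1.0 <= out.iloc[0]["icc"] <= 1.0


def test_summary_table_descriptive_only():
    rng = np.random.default_rng(2)
    table = _toy_table(rng)
    out = sa.summary_table(table[table.method == "automated"])
    assert "all" in out.columns


def test_summary_table_validates_schema():
    with pytest.raises(ValueError):
        sa.summary_table(pd.DataFrame({"foo": [1]}))


def test_holm_adjustment_monotone():
    rng = np.random.default_rng(3)
    rows = []
    for param in ("a", "b", "c"):
        for ear in range(12):
            sex = "F" if ear % 2 else "M"
            rows.append(dict(ear_id=ear, sex=sex, parameter=param, method="automated",
                             replicate=0, value=rng.normal(5 + (sex == "M"), 1)))
    out = sa.summary_table(pd.DataFrame(rows), grouping="sex", holm=True)
    assert np.all(out["p_holm"] >= out["p_value"] - 1e-15)
    assert np.all(out["p_holm"] <= 1.0)
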