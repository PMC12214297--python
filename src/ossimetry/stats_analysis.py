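"""Statistical workflow for replicate consistency and group comparisons.

Mirrors the analysis plan used for ossicular-chain measurement studies:

* ICC(3,1) — two-way mixed, consistency, single measurement — for the
  agreement of repeated manual measurements and for manual-vs-automated
  agreement (< 0.4 poor, > 0.75 high consistency).
* Paired comparisons: Shapiro–Wilk on the differences gates a paired t test
  (normal) versus the Wilcoxon signed-rank test.
* Two-group comparisons: per-group normality gates an independent t test
  (Welch-corrected when Levene rejects equal variances) versus Mann–Whitney U.
* >= 3 groups: per-group normality plus Levene homogeneity gate one-way
  ANOVA versus Kruskal–Wallis.
* Pearson chi-square goodness of fit for demographic counts.

The significance threshold alpha defaults to 0.05 throughout. No
multiple-testing correction is applied by default (a Holm adjustment is
available as an option on the summary table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05

REQUIRED_COLUMNS = ("ear_id", "parameter", "method", "replicate", "value")


@dataclass
class ICCResult:
    icc_value: float
    model_tag: str
    n_subjects: int
    n_raters: int

    @property
    def consistency_band(self) -> str:
        if self.icc_value < 0.4:
            return "poor"
        if self.icc_value > 0.75:
            return "high"
        return "moderate"


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    normality_used: bool
    group_labels: tuple = ()
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def icc_consistency(values: np.ndarray) -> ICCResult:
    """ICC(3,1) from the two-way ANOVA decomposition of a subjects x
    replicates matrix (no missing cells).

    ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k - 1) MS_error); equal
    replicate columns give exactly 1, pure replicate noise with constant
    subjects gives ~0 or negative.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x replicates matrix with >= 2 of each")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err <= 1e-30:
        icc = 1.0 if ms_rows > 0 else 0.0
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return ICCResult(icc_value=float(icc), model_tag="ICC(3,1) two-way mixed, "
                     "consistency, single", n_subjects=n, n_raters=k)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # Shapiro is undefined for constant data
        return False
    return sps.shapiro(x).pvalue > alpha


def paired_comparison(x, y, alpha: float = ALPHA_DEFAULT) -> ComparisonResult:
    """Paired t test or Wilcoxon signed-rank, gated by normality of the
    differences; exact-equality short-circuits to p = 1 with a flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired comparison needs equal-length vectors of n >= 3")
    diff = x - y
    if np.ptp(diff) == 0 and diff[0] == 0:
        return ComparisonResult("exact-equality", 0.0, 1.0, len(x), False,
                                flags=["all differences are zero"])
    if _is_normal(diff, alpha):
        res = sps.ttest_rel(x, y)
        return ComparisonResult("paired t", float(res.statistic), float(res.pvalue),
                                len(x), True)
    res = sps.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return ComparisonResult("Wilcoxon signed-rank", float(res.statistic),
                            float(res.pvalue), len(x), False)


def group_comparison(x, y, alpha: float = ALPHA_DEFAULT) -> ComparisonResult:
    """Independent-samples comparison of two groups.

    Normal in both groups -> t test (Welch correction when Levene rejects
    variance equality at 0.05); otherwise Mann–Whitney U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(np.concatenate([x, y])) == 0:
        return ComparisonResult("exact-tie", 0.0, 1.0, len(x) + len(y), False,
                                flags=["all values identical"])
    if _is_normal(x, alpha) and _is_normal(y, alpha):
        equal_var = sps.levene(x, y).pvalue > 0.05
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        name = "independent t" if equal_var else "Welch t"
        return ComparisonResult(name, float(res.statistic), float(res.pvalue),
                                len(x) + len(y), True)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult("Mann-Whitney U", float(res.statistic), float(res.pvalue),
                            len(x) + len(y), False)


def multi_group_comparison(groups, alpha: float = ALPHA_DEFAULT) -> ComparisonResult:
    """One-way ANOVA when every group is normal and variances are homogeneous
    (Levene at 0.05); Kruskal–Wallis otherwise."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("multi-group comparison needs >= 3 groups")
    if any(g.ndim != 1 or len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return ComparisonResult("exact-tie", 0.0, 1.0, len(pooled), False,
                                flags=["all values identical"])
    normal = all(_is_normal(g, alpha) for g in groups)
    homogeneous = sps.levene(*groups).pvalue > 0.05 if normal else False
    if normal and homogeneous:
        res = sps.f_oneway(*groups)
        return ComparisonResult("one-way ANOVA", float(res.statistic),
                                float(res.pvalue), len(pooled), True,
                                flags=["gates: normal+homogeneous"])
    res = sps.kruskal(*groups)
    return ComparisonResult("Kruskal-Wallis", float(res.statistic), float(res.pvalue),
                            len(pooled), False,
                            flags=[f"gates: normal={normal}, homogeneous={homogeneous}"])


def chi_square_gof(observed, expected_proportions=None) -> ComparisonResult:
    """Pearson chi-square goodness of fit (default: uniform proportions)."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) < 2 or np.any(obs < 0):
        raise ValueError("observed must be a vector of non-negative counts")
    total = obs.sum()
    if total <= 0:
        raise ValueError("all-zero counts")
    if expected_proportions is None:
        exp = np.full(len(obs), total / len(obs))
    else:
        props = np.asarray(expected_proportions, dtype=float)
        exp = props / props.sum() * total
    res = sps.chisquare(obs, exp)
    return ComparisonResult("chi-square GOF", float(res.statistic), float(res.pvalue),
                            int(total), False)


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------

def format_mean_sd(values, decimals: int = 2) -> str:
    """'mean ± SD' at fixed decimals (sample SD, ddof=1)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    return f"{v.mean():.{decimals}f} ± {sd:.{decimals}f}"

def format_percent(count: int, total: int, decimals: int = 1) -> str:
    """Percentage string as printed in demographic tables: 75/140 -> '53.6'."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{100.0 * count / total:.{decimals}f}"


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns: {missing}")
    dup = table.duplicated(subset=["ear_id", "parameter", "method", "replicate"])
    if dup.any():
        raise ValueError("duplicate (ear_id, parameter, method, replicate) rows")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite measurement values")


def summary_table(
    table: pd.DataFrame,
    grouping: str | None = None,
    compare_methods: bool = False,
    alpha: float = ALPHA_DEFAULT,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-parameter descriptive/comparison report.

    ``grouping`` names a column (e.g. sex / side / age_group): cells show
    'mean ± SD' per group plus the gated two-or-k-group test. With
    ``compare_methods`` the manual and automated columns are compared with
    the gated paired test and their agreement ICC. Empty groups are reported
    as NA. ``holm`` applies a Holm step-down adjustment to the p column.
    """
    validate_table(table)
    rows = []
    for param, sub in table.groupby("parameter", sort=True):
        # average replicates within ear & method first (the reported value)
        per_ear = (sub.groupby(["ear_id", "method"])["value"].mean().reset_index())
        row: dict[str, object] = {"parameter": param}
        if compare_methods:
            wide = per_ear.pivot(index="ear_id", columns="method", values="value")
            if {"manual", "automated"} <= set(wide.columns):
                both = wide.dropna(subset=["manual", "automated"])
                row["manual"] = format_mean_sd(both["manual"])
                row["automated"] = format_mean_sd(both["automated"])
                cmp_res = paired_comparison(both["manual"], both["automated"], alpha)
                row["test"] = cmp_res.test_name
                row["statistic"] = round(cmp_res.statistic, 3)
                row["p_value"] = cmp_res.p_value
                row["icc"] = round(
                    icc_consistency(both[["manual", "automated"]].to_numpy()).icc_value, 3
                )
            else:
                row["test"] = "NA"
        elif grouping is not None:
            if grouping not in sub.columns:
                raise ValueError(f"grouping column {grouping!r} not in table")
            merged = sub.groupby(["ear_id", grouping])["value"].mean().reset_index()
            groups = {g: d["value"].to_numpy() for g, d in merged.groupby(grouping)}
            vecs = []
            for g, vals in groups.items():
                row[str(g)] = format_mean_sd(vals) if len(vals) else "NA"
                if len(vals):
                    vecs.append(vals)
            if len(vecs) < len(groups):
                row["test"] = "NA"
            elif len(vecs) == 2:
                cmp_res = group_comparison(vecs[0], vecs[1], alpha)
                row["test"], row["statistic"], row["p_value"] = (
                    cmp_res.test_name, round(cmp_res.statistic, 3), cmp_res.p_value)
            elif len(vecs) >= 3:
                cmp_res = multi_group_comparison(vecs, alpha)
                row["test"], row["statistic"], row["p_value"] = (
                    cmp_res.test_name, round(cmp_res.statistic, 3), cmp_res.p_value)
            else:
                row["test"] = "NA"
        else:
            row["all"] = format_mean_sd(per_ear["value"])
        rows.append(row)
    out = pd.DataFrame(rows)
    if holm and "p_value" in out.columns:
        p = out["p_value"].to_numpy(dtype=float)
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        m = len(p)
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        out["p_holm"] = adj
    return out


def table_to_markdown(table: pd.DataFrame) -> str:
    return table.to_markdown(index=False)
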