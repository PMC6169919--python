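"""The study's inference layer for long-format cohort tables.

A cohort table is a tidy DataFrame with one row per specimen × outcome:
columns ``specimen``, ``group``, a time column (``week`` or ``day``),
``outcome`` and ``value``.  The battery mirrors a classic longitudinal
preclinical design: unpaired t-tests per time point with percent
changes, paired t-tests for the contralateral-control design, ANCOVA
with a treatment×time interaction, one-way ANOVA with Tukey HSD,
ordinary least-squares regressions and Cohen's d effect sizes.

No multiple-testing correction is applied across time points or
outcomes; set ``alpha`` consciously and treat the per-comparison p
values accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError


def percent_change(treated_mean: float, reference_mean: float) -> float:
    """Signed percent change, ``(treated - reference) / reference * 100``."""
    if reference_mean == 0:
        raise InputError("reference mean is zero; percent change undefined")
    return (float(treated_mean) - float(reference_mean)) / float(reference_mean) * 100.0


def timepoint_tests(
    table: pd.DataFrame,
    outcome: str,
    reference: str = "Sham",
    treated: str = "RTx",
    time_col: str = "week",
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided unpaired t-test of treated vs reference at each time point.

    Returns one row per time point with group descriptives (mean, SD, n),
    the t statistic, p value, percent change of group means and a
    significance star at ``p < alpha``.  ``equal_var=False`` switches to
    Welch's test.
    """
    sub = table[table["outcome"] == outcome]
    if sub.empty:
        raise InputError(f"outcome {outcome!r} not present in table")
    rows = []
    for t, cell in sub.groupby(time_col):
        a = cell.loc[cell["group"] == reference, "value"].to_numpy(float)
        b = cell.loc[cell["group"] == treated, "value"].to_numpy(float)
        if a.size < 2 or b.size < 2:
            raise InputError(
                f"need n >= 2 in both groups at {time_col}={t}; "
                f"got {a.size} and {b.size}"
            )
        res = sps.ttest_ind(b, a, equal_var=equal_var)
        rows.append(
            {
                time_col: t,
                f"n_{reference}": a.size,
                f"mean_{reference}": a.mean(),
                f"sd_{reference}": a.std(ddof=1),
                f"n_{treated}": b.size,
                f"mean_{treated}": b.mean(),
                f"sd_{treated}": b.std(ddof=1),
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "percent_change": percent_change(b.mean(), a.mean()),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows).set_index(time_col)


def paired_tests(
    table: pd.DataFrame,
    outcome: str,
    reference: str = "control",
    treated: str = "RTx",
    pair_col: str = "animal",
) -> dict:
    """Two-sided paired t-test (treated vs contralateral reference femur).

    Pairs are matched on ``pair_col``; incomplete pairs raise.  Returns
    the t statistic, p value, mean paired difference and the percent
    change of the treated mean relative to the reference mean.
    """
    sub = table[table["outcome"] == outcome]
    if sub.empty:
        raise InputError(f"outcome {outcome!r} not present in table")
    wide = sub.pivot_table(index=pair_col, columns="group", values="value")
    if reference not in wide or treated not in wide:
        raise InputError(f"groups {reference!r}/{treated!r} not both present")
    if wide[[reference, treated]].isna().any().any():
        broken = wide.index[wide[[reference, treated]].isna().any(axis=1)].tolist()
        raise InputError(f"broken pairs for {pair_col} in {broken}")
    a = wide[reference].to_numpy(float)
    b = wide[treated].to_numpy(float)
    diff = b - a
    if np.std(diff, ddof=1) == 0:
        # degenerate but well-defined: identical pairs carry no evidence
        t_stat = 0.0 if diff.mean() == 0 else math.copysign(math.inf, diff.mean())
        p_val = 1.0 if diff.mean() == 0 else 0.0
    else:
        res = sps.ttest_rel(b, a)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return {
        "n_pairs": int(a.size),
        "t": t_stat,
        "p": p_val,
        "mean_difference": float(np.mean(b - a)),
        "percent_change": percent_change(b.mean(), a.mean()),
    }


@dataclass(frozen=True)
class AncovaResult:
    """ANCOVA of outcome on treatment with time as covariate.

    p values are the treatment main effect, the time covariate and the
    treatment×time interaction from the full-interaction model; R² is
    the full-model fit.  ``common_time_slope`` is the shared time slope
    from the additive (no-interaction) refit — the quantity reported
    when the interaction is retained-but-nonsignificant.
    """

    p_treatment: float
    p_time: float
    p_interaction: float
    r_squared: float
    common_time_slope: float

    def summary(self) -> str:
        return (
            f"treatment p={self.p_treatment:.4g}  time p={self.p_time:.4g}  "
            f"interaction p={self.p_interaction:.4g}  R2={self.r_squared:.3f}  "
            f"common slope={self.common_time_slope:.4g}/wk"
        )


def ancova(
    table: pd.DataFrame,
    outcome: str,
    reference: str = "Sham",
    time_col: str = "week",
) -> AncovaResult:
    """Fit ``value ~ treatment * time`` and report the three p values.

    Requires at least two time points per group (otherwise the slope is
    unidentified and the fit is rank deficient).
    """
    sub = table[table["outcome"] == outcome].copy()
    if sub.empty:
        raise InputError(f"outcome {outcome!r} not present in table")
    if (sub.groupby("group")[time_col].nunique() < 2).any():
        raise InputError("ANCOVA needs >= 2 time points in every group")
    sub["time"] = sub[time_col].astype(float)
    grp = f"C(group, Treatment(reference={reference!r}))"
    full = smf.ols(f"value ~ {grp} * time", data=sub).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise InputError("rank-deficient design; check group/time coding")
    additive = smf.ols(f"value ~ {grp} + time", data=sub).fit()

    def _p(pattern: str) -> float:
        hits = [n for n in full.params.index if pattern == n]
        if len(hits) != 1:
            raise InputError(f"could not locate term {pattern!r} in the fit")
        return float(full.pvalues[hits[0]])

    other = [g for g in sub["group"].unique() if g != reference]
    if len(other) != 1:
        raise InputError("ANCOVA expects exactly two groups")
    trt_term = f"{grp}[T.{other[0]}]"
    return AncovaResult(
        p_treatment=_p(trt_term),
        p_time=_p("time"),
        p_interaction=_p(f"{trt_term}:time"),
        r_squared=float(full.rsquared),
        common_time_slope=float(additive.params["time"]),
    )


@dataclass(frozen=True)
class AnovaTukeyResult:
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA omnibus test with Tukey HSD pairwise comparisons."""
    if len(groups) < 3:
        raise InputError("need >= 3 groups for ANOVA + Tukey")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    omnibus = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[c.strip() for c in hsd.summary().data[0]],
    ).rename(
        columns={
            "group1": "group_a", "group2": "group_b",
            "meandiff": "mean_diff", "p-adj": "p_adj",
        }
    )
    frame["p_adj"] = hsd.pvalues  # full precision, not the rounded table
    return AnovaTukeyResult(omnibus_p=float(omnibus.pvalue), pairwise=frame)


@dataclass(frozen=True)
class LinFitResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    stderr: float


def linfit(x, y) -> LinFitResult:
    """OLS line with the two-sided slope test (e.g. toughness vs ribose days)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need >= 3 paired points")
    if np.var(x) == 0:
        raise InputError("x is degenerate (zero variance)")
    fit = sps.linregress(x, y)
    return LinFitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


@dataclass(frozen=True)
class EffectSize:
    d: float
    magnitude: str  # negligible / small / medium / large


def cohens_d(group_a, group_b) -> EffectSize:
    """Cohen's d: mean difference over the pooled SD, with a size class.

    Classes at |d| >= 0.2 / 0.5 / 0.8 for small / medium / large.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("need n >= 2 in both groups")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise InputError("pooled SD is zero; effect size undefined")
    d = float((a.mean() - b.mean()) / pooled)
    mag = abs(d)
    if mag >= 0.8:
        cls = "large"
    elif mag >= 0.5:
        cls = "medium"
    elif mag >= 0.2:
        cls = "small"
    else:
        cls = "negligible"
    return EffectSize(d=d, magnitude=cls)
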