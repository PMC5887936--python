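"""Foot-volume computation and the group statistics of the paw study.

Volumes come from per-slice outlined areas (2 mm proton image slices,
summed area x thickness). Group inference follows the study design being
reproduced: a one-sided Welch t-test for the pH comparison between inflamed
and non-inflamed paws, and a two-way (treatment x day) fixed-effects ANOVA
with Sidak-adjusted per-day comparisons for the swelling and clinical-score
time courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "SliceAreaSet",
    "GroupComparison",
    "AnovaSidakResult",
    "foot_volume",
    "welch_statistic",
    "one_sided_t_test",
    "sidak_adjust",
    "two_way_anova_sidak",
]

Alternative = Literal["less", "greater", "two-sided"]


@dataclass(frozen=True)
class SliceAreaSet:
    """Per-slice outlined areas (cm^2) with a common slice thickness (cm)."""

    areas_cm2: tuple[float, ...]
    thickness_cm: float = 0.2

    def __post_init__(self) -> None:
        if len(self.areas_cm2) < 1:
            raise ValueError("at least one slice area is required")
        if any(a < 0 for a in self.areas_cm2):
            raise ValueError("slice areas must be >= 0")
        if self.thickness_cm <= 0:
            raise ValueError("thickness_cm must be > 0")


def foot_volume(slices: SliceAreaSet) -> float:
    """Whole-foot volume: sum of slice areas times slice thickness (cm^3)."""
    return float(np.sum(slices.areas_cm2) * slices.thickness_cm)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group t-test result with the summary statistics that produced it."""

    statistic: float
    df: float
    p: float
    alternative: Alternative
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    pooled: bool = False


def welch_statistic(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Welch t statistic and Welch–Satterthwaite df from summary statistics."""
    va = sd_a**2 / n_a
    vb = sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(t), float(df)


def _p_from_t(t: float, df: float, alternative: Alternative) -> float:
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    return float(2 * stats.t.sf(abs(t), df))


def one_sided_t_test(
    group_a: Sequence[float] | None = None,
    group_b: Sequence[float] | None = None,
    alternative: Alternative = "less",
    summary_a: tuple[float, float, int] | None = None,
    summary_b: tuple[float, float, int] | None = None,
    pooled: bool = False,
) -> GroupComparison:
    """Two-sample t-test (Welch by default) with a one-sided alternative.

    ``alternative="less"`` tests mean_a < mean_b. Accepts either raw samples
    or (mean, sd, n) summary triples, so tests reported only as printed
    summaries can be recomputed exactly.
    """
    if summary_a is not None or summary_b is not None:
        if summary_a is None or summary_b is None:
            raise ValueError("provide both summary_a and summary_b")
        mean_a, sd_a, n_a = summary_a
        mean_b, sd_b, n_b = summary_b
    else:
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        mean_a, sd_a, n_a = float(a.mean()), float(a.std(ddof=1)), len(a)
        mean_b, sd_b, n_b = float(b.mean()), float(b.std(ddof=1)), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if pooled:
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = float(n_a + n_b - 2)
    else:
        t, df = welch_statistic(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    p = _p_from_t(float(t), df, alternative)
    return GroupComparison(
        statistic=float(t), df=df, p=p, alternative=alternative,
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b, n_a=n_a, n_b=n_b,
        pooled=pooled,
    )


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiplicity adjustment: p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m if np.ndim(p) else float(
        1.0 - (1.0 - p) ** m
    )


@dataclass
class AnovaSidakResult:
    """Two-way ANOVA effects plus Sidak-adjusted per-day comparisons."""

    anova_table: pd.DataFrame
    per_day: pd.DataFrame
    value_col: str

    def summary(self) -> str:
        out = [
            f"Two-way ANOVA on '{self.value_col}' (treatment x day)",
            self.anova_table.to_string(),
            "",
            "Per-day comparisons (Sidak-adjusted):",
            self.per_day.to_string(index=False),
        ]
        return "\n".join(out)


def two_way_anova_sidak(
    table: pd.DataFrame,
    value_col: str,
    treatment_col: str = "side",
    day_col: str = "day",
    per_day_method: Literal["pooled", "welch"] = "pooled",
) -> AnovaSidakResult:
    """Two-way fixed-effects ANOVA with Sidak-adjusted per-day comparisons.

    Fits ``value ~ C(treatment) * C(day)`` by OLS (type-II sums of squares)
    and compares the two treatment levels at each day. With
    ``per_day_method="pooled"`` the per-day tests use the pooled residual
    mean square of the ANOVA (the convention of common stats packages for
    post-hoc comparisons); ``"welch"`` uses per-day Welch tests instead.
    Sidak adjustment uses m = number of days.
    """
    for col, name in ((treatment_col, "treatment"), (day_col, "day")):
        if table[col].nunique() < 2:
            raise ValueError(f"{name} factor '{col}' must have at least 2 levels")
    levels = sorted(table[treatment_col].unique())
    if len(levels) != 2:
        raise ValueError("exactly two treatment levels are required")

    df = table.rename(columns={value_col: "_y"})
    model = ols(f"_y ~ C({treatment_col}) * C({day_col})", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    mse = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    df_resid = float(anova.loc["Residual", "df"])
    days = sorted(table[day_col].unique())
    m = len(days)
    rows = []
    for day in days:
        sub = table[table[day_col] == day]
        a = sub.loc[sub[treatment_col] == levels[0], value_col].to_numpy(float)
        b = sub.loc[sub[treatment_col] == levels[1], value_col].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"day {day}: each treatment level needs n >= 2")
        diff = a.mean() - b.mean()
        if per_day_method == "pooled":
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = diff / se
            ddf = df_resid
        else:
            t, ddf = welch_statistic(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
        p = _p_from_t(float(t), float(ddf), "two-sided")
        rows.append(
            {
                "day": day,
                f"mean_{levels[0]}": a.mean(),
                f"mean_{levels[1]}": b.mean(),
                "mean_diff": diff,
                "t": float(t),
                "df": float(ddf),
                "p_raw": p,
                "p_sidak": sidak_adjust(p, m),
            }
        )
    per_day = pd.DataFrame(rows)

    # Name the effect rows by role for downstream consumers.
    anova = anova.rename(
        index={
            f"C({treatment_col})": "treatment",
            f"C({day_col})": "day",
            f"C({treatment_col}):C({day_col})": "interaction",
        }
    )
    return AnovaSidakResult(anova_table=anova, per_day=per_day, value_col=value_col)
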