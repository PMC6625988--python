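"""Xenograft growth-curve evaluation and group statistics.

Tumor volume is estimated from two orthogonal caliper diameters a and b via
the mean diameter l = √(a·b):

    V = (π/6)·l³ = (π/6)·(a·b)^(3/2)   [mm³]

Growth is summarized as the percent volume change of each mouse against its
own day-0 volume, optionally renormalized so that the control group's
final-day mean change reads 100%.  Group comparisons use Student's t
(two groups, one day), one-way ANOVA (>2 groups, one day) and a fixed-effects
two-way ANOVA (group × day, Type II sums of squares, tolerating mild
imbalance from animals lost during the study).  Significance is called at
p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import InsufficientDataError, SchemaError

__all__ = [
    "TumorMeasurements",
    "GrowthSummary",
    "tumor_volume",
    "growth_summary",
    "compare_groups",
    "power_two_sample",
    "achieved_power",
]


def tumor_volume(a: float, b: float) -> float:
    """Volume (mm³) from two orthogonal diameters (mm); symmetric in a, b."""
    if a < 0 or b < 0:
        raise ValueError(f"diameters must be nonnegative, got a={a}, b={b}")
    return (math.pi / 6.0) * (a * b) ** 1.5


@dataclass
class TumorMeasurements:
    """Longitudinal caliper records: mouse_id, group, day, diameter_a, diameter_b."""

    records: pd.DataFrame

    REQUIRED = ("mouse_id", "group", "day", "diameter_a", "diameter_b")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise SchemaError(f"tumor table missing column '{col}'", column=col)
        if (self.records[["diameter_a", "diameter_b"]] < 0).any().any():
            raise SchemaError("negative diameters", column="diameter_a")
        dup = self.records.duplicated(subset=["mouse_id", "day"])
        if dup.any():
            raise SchemaError("duplicate (mouse, day) records", column="day")

    def volumes(self) -> pd.DataFrame:
        df = self.records.copy()
        df["volume"] = [
            tumor_volume(a, b) for a, b in zip(df["diameter_a"], df["diameter_b"])
        ]
        return df


@dataclass
class GrowthSummary:
    """Per-mouse volumes/percent changes and per-group day-wise statistics."""

    per_mouse: pd.DataFrame  # mouse_id, group, day, volume, pct_change
    per_group: pd.DataFrame  # group, day, mean_pct_change, sd_pct_change, n
    control_normalized: pd.DataFrame | None = None
    excluded_mice: list[str] = field(default_factory=list)


def growth_summary(tm: TumorMeasurements, control_group: str | None = None) -> GrowthSummary:
    """Percent volume change vs day 0 per mouse; group mean ± sd per day.

    Mice lacking a day-0 record are excluded with a warning.  When
    ``control_group`` is given, group means are also expressed as a percent
    of that group's final-day mean change.
    """
    df = tm.volumes()
    excluded = []
    frames = []
    for mouse, sub in df.groupby("mouse_id", sort=False):
        day0 = sub[sub["day"] == 0]
        if day0.empty:
            excluded.append(str(mouse))
            warnings.warn(f"mouse {mouse} has no day-0 record; excluded")
            continue
        v0 = float(day0["volume"].iloc[0])
        if v0 <= 0:
            raise ValueError(f"mouse {mouse}: day-0 volume must be positive, got {v0}")
        s = sub.copy()
        s["pct_change"] = 100.0 * (s["volume"] - v0) / v0
        frames.append(s)
    if not frames:
        raise InsufficientDataError("no mouse has a day-0 record")
    per_mouse = pd.concat(frames, ignore_index=True)
    per_group = (
        per_mouse.groupby(["group", "day"])["pct_change"]
        .agg(mean_pct_change="mean", sd_pct_change="std", n="count")
        .reset_index()
    )
    control_normalized = None
    if control_group is not None:
        ctl = per_group[per_group["group"] == control_group]
        if ctl.empty:
            raise ValueError(f"control group '{control_group}' not found")
        final_day = ctl["day"].max()
        ref = float(ctl.loc[ctl["day"] == final_day, "mean_pct_change"].iloc[0])
        if ref == 0:
            raise ValueError("control final-day mean change is zero; cannot normalize")
        control_normalized = per_group.copy()
        control_normalized["mean_pct_of_control_final"] = (
            100.0 * control_normalized["mean_pct_change"] / ref
        )
    return GrowthSummary(
        per_mouse=per_mouse,
        per_group=per_group,
        control_normalized=control_normalized,
        excluded_mice=excluded,
    )


@dataclass
class StatsReport:
    test: str
    statistic: float
    p_value: float
    significant: bool
    details: dict = field(default_factory=dict)


def _day_slice(gs: GrowthSummary, groups, day) -> list[np.ndarray]:
    out = []
    for g in groups:
        vals = gs.per_mouse.loc[
            (gs.per_mouse["group"] == g) & (gs.per_mouse["day"] == day), "pct_change"
        ].to_numpy(float)
        if len(vals) < 2:
            raise InsufficientDataError(
                f"group '{g}' has {len(vals)} mice at day {day}; need >=2"
            )
        out.append(vals)
    return out


def compare_groups(
    gs: GrowthSummary,
    kind: str = "ttest",
    groups: list[str] | None = None,
    day: float | None = None,
    alpha: float = 0.05,
) -> StatsReport:
    """Group comparison on percent volume change.

    kind='ttest'  — two-sample Student's t, two groups at one day;
    kind='anova1' — one-way ANOVA across >2 groups at one day;
    kind='anova2' — two-way fixed-effects ANOVA, group × day, Type II SS,
                    on all groups/days (or the subsets given).
    """
    all_groups = list(gs.per_mouse["group"].unique())
    groups = groups if groups is not None else all_groups
    if len(groups) < 2:
        raise InsufficientDataError("need >=2 groups to compare")

    if kind == "ttest":
        if len(groups) != 2:
            raise ValueError("ttest compares exactly two groups")
        if day is None:
            day = float(gs.per_mouse["day"].max())
        x, y = _day_slice(gs, groups, day)
        t, p = stats.ttest_ind(x, y)
        return StatsReport("two-sample t", float(t), float(p), p < alpha, {"day": day})

    if kind == "anova1":
        if day is None:
            day = float(gs.per_mouse["day"].max())
        arrays = _day_slice(gs, groups, day)
        f, p = stats.f_oneway(*arrays)
        return StatsReport("one-way ANOVA", float(f), float(p), p < alpha, {"day": day})

    if kind == "anova2":
        df = gs.per_mouse[gs.per_mouse["group"].isin(groups)].copy()
        if day is not None:
            raise ValueError("two-way ANOVA uses all days; do not pass a single day")
        counts = df.groupby(["group", "day"])["pct_change"].count()
        if (counts < 2).any():
            raise InsufficientDataError("every group x day cell needs >=2 mice")
        df["day_f"] = df["day"].astype(str)
        model = smf.ols("pct_change ~ C(group) * C(day_f)", data=df).fit()
        table = anova_lm(model, typ=2)
        p = float(table.loc["C(group)", "PR(>F)"])
        f = float(table.loc["C(group)", "F"])
        return StatsReport(
            "two-way ANOVA (group x day)",
            f,
            p,
            p < alpha,
            {"anova_table": table, "interaction_p": float(table.loc["C(group):C(day_f)", "PR(>F)"])},
        )

    raise ValueError(f"unknown comparison kind '{kind}'")


def achieved_power(n: int, effect: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test with n per group, via the
    noncentral-t distribution (noncentrality effect·√(n/2), df 2n−2)."""
    df = 2 * n - 2
    nc = effect * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def power_two_sample(
    effect: float, alpha: float = 0.05, power: float = 0.8, n_max: int = 10_000
) -> int:
    """Smallest n per group for a two-sided two-sample t-test to reach the
    target power at standardized difference ``effect``."""
    if effect <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if achieved_power(n, effect, alpha) >= power:
            return n
    raise InsufficientDataError(f"no n <= {n_max} achieves power {power}")
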