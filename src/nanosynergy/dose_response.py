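"""Viability normalization and single-drug dose–response fitting.

Raw fluorescence intensities are normalized to percent viability against the
untreated control's mean.  Single-drug curves are then fitted in two
complementary forms:

* the four-parameter logistic (4PL), v(D) = d + (a−d)/(1 + (D/c)^b), whose
  inflection dose c is reported as the IC50; and
* the median-effect model, fa/(1−fa) = (D/Dm)^m, fitted by ordinary least
  squares of log10(fa/(1−fa)) on log10(D), which supplies the (m, Dm)
  parameters the combination-index machinery needs.

When the asymptotes span 100 → 0 the two forms describe the same Hill curve
and c coincides with Dm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ConditionSet
from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    NormalizationError,
    SchemaError,
)

__all__ = [
    "ViabilityTable",
    "FourPLFit",
    "MedianEffectFit",
    "normalize_to_control",
    "fit_four_param_logistic",
    "fit_median_effect",
    "single_drug_profiles",
    "fit_all_single_drugs",
]


@dataclass
class ViabilityTable:
    """Per-condition, per-replicate percent viability linked to its design.

    ``records`` columns: condition_id, replicate, viability (percent of the
    untreated control; fraction affected fa = 1 − viability/100).
    """

    records: pd.DataFrame
    design: ConditionSet

    REQUIRED = ("condition_id", "replicate", "viability")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise SchemaError(f"viability table missing column '{col}'", column=col)
        if (self.records["viability"] < 0).any():
            raise SchemaError("negative viability values", column="viability")
        known = {c.id for c in self.design.conditions}
        unknown = set(self.records["condition_id"]) - known
        if unknown:
            raise SchemaError(
                f"condition ids not in design: {sorted(unknown)[:5]}",
                column="condition_id",
            )

    def mean_viability(self) -> pd.Series:
        """Mean percent viability per condition, replicates pooled."""
        return self.records.groupby("condition_id")["viability"].mean()

    def fraction_affected(self) -> pd.Series:
        """Mean fa = 1 − viability/100 per condition."""
        return 1.0 - self.mean_viability() / 100.0


@dataclass
class FourPLFit:
    """Four-parameter logistic fit; ``c`` is the IC50 (μg/ml)."""

    a: float  # upper asymptote (%)
    d: float  # lower asymptote (%)
    c: float  # inflection dose = IC50
    b: float  # slope
    rss: float
    converged: bool

    @property
    def ic50(self) -> float:
        return self.c

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (dose / self.c) ** self.b, 0.0)
        return self.d + (self.a - self.d) / (1.0 + ratio)


@dataclass
class MedianEffectFit:
    """Median-effect parameters from the log–log (logit) linearization."""

    drug: str
    m_slope: float
    dm: float  # dose at fa = 0.5 (μg/ml)
    r: float  # correlation coefficient of the linear fit
    n_points: int
    n_excluded: int = 0

    def fraction_affected(self, dose):
        """fa(D) = 1/(1 + (Dm/D)^m); 0 at zero dose."""
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            fa = np.where(dose > 0, 1.0 / (1.0 + (self.dm / np.maximum(dose, 1e-300)) ** self.m_slope), 0.0)
        return fa


def normalize_to_control(
    raw: pd.DataFrame, control_ids, design: ConditionSet | None = None
) -> pd.DataFrame | ViabilityTable:
    """Normalize raw intensities to percent of the untreated-control mean.

    ``raw`` needs columns condition_id, replicate, intensity.  The control
    mean maps to exactly 100%.  Returns a ViabilityTable when a design is
    supplied, otherwise the bare records frame.
    """
    for col in ("condition_id", "replicate", "intensity"):
        if col not in raw.columns:
            raise SchemaError(f"intensity table missing column '{col}'", column=col)
    control_ids = set(control_ids)
    ctl = raw.loc[raw["condition_id"].isin(control_ids), "intensity"]
    if ctl.empty:
        raise NormalizationError("no control replicates found")
    ctl_mean = float(ctl.mean())
    if ctl_mean <= 0:
        raise NormalizationError(f"control mean intensity must be positive, got {ctl_mean}")
    out = raw[["condition_id", "replicate"]].copy()
    out["viability"] = 100.0 * raw["intensity"] / ctl_mean
    if design is not None:
        return ViabilityTable(records=out, design=design)
    return out


def _four_pl(dose, a, d, c, b):
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / c) ** b, 0.0)
    return d + (a - d) / (1.0 + ratio)


def fit_four_param_logistic(doses, viabilities) -> FourPLFit:
    """Unweighted least-squares 4PL fit.

    Requires ≥4 distinct positive doses; zero-dose points are kept and
    anchor the upper asymptote.  Non-convergence is flagged on the result,
    never silent; a flat response raises :class:`DegenerateFitError`.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if doses.shape != viab.shape:
        raise InsufficientDataError("doses and viabilities must have equal length")
    if not np.all(np.isfinite(viab)):
        raise InsufficientDataError("viabilities must be finite")
    n_distinct = len(np.unique(doses[doses > 0]))
    if n_distinct < 4:
        raise InsufficientDataError(
            f"need >=4 distinct positive doses for a 4PL fit, got {n_distinct}"
        )
    if np.ptp(viab) < 1e-9:
        raise DegenerateFitError("viability is constant across doses; no curve to fit")

    pos = doses[doses > 0]
    # init: a=max, d=min, c=geometric mean of positive doses, b=1
    p0 = [float(viab.max()), float(viab.min()), float(np.exp(np.mean(np.log(pos)))), 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, -50.0], [np.inf, np.inf, np.inf, 50.0])
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, doses, viab, p0=p0, bounds=bounds, maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    a, d, c, b = (float(x) for x in popt)
    if a < d:  # canonical orientation: a is the upper asymptote
        a, d, b = d, a, -b
    rss = float(np.sum((_four_pl(doses, a, d, c, b) - viab) ** 2))
    return FourPLFit(a=a, d=d, c=c, b=b, rss=rss, converged=converged)


def fit_median_effect(doses, viabilities, drug: str = "") -> MedianEffectFit:
    """OLS fit of log10(fa/(1−fa)) on log10(D).

    Points with D = 0 or fa outside the open interval (0, 1) are excluded
    (not clipped — clipping would bias the logit fit) and counted in
    ``n_excluded``.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    fa = 1.0 - viab / 100.0
    usable = (doses > 0) & (fa > 0) & (fa < 1)
    n_excluded = int((~usable).sum())
    d_use, fa_use = doses[usable], fa[usable]
    if len(d_use) < 2 or len(np.unique(d_use)) < 2:
        raise InsufficientDataError(
            f"need >=2 usable points at >=2 distinct positive doses, got {len(d_use)}"
        )
    x = np.log10(d_use)
    y = np.log10(fa_use / (1.0 - fa_use))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise DegenerateFitError(f"non-positive median-effect slope m={m:.3g}")
    dm = float(10.0 ** (-res.intercept / m))
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectFit(
        drug=drug, m_slope=m, dm=dm, r=r, n_points=int(len(d_use)), n_excluded=n_excluded
    )


def single_drug_profiles(vt: ViabilityTable) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Extract per-drug (dose, viability) arrays from single-role conditions.

    Replicates enter as separate points (pooled, not averaged first).
    """
    df = vt.records.merge(vt.design.to_frame(), on="condition_id")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for drug in vt.design.drug_names:
        sub = df[(df["role"] == "single") & (df[drug] > 0)]
        out[drug] = (sub[drug].to_numpy(float), sub["viability"].to_numpy(float))
    return out


def fit_all_single_drugs(
    vt: ViabilityTable, on_error: str = "raise"
) -> dict[str, MedianEffectFit]:
    """Median-effect fit per drug from the screen's single-drug conditions.

    With ``on_error='skip'`` drugs whose fit fails (e.g. a near-inert drug
    whose noisy fa values carry no dose signal) are omitted from the result
    instead of aborting the screen analysis.
    """
    fits: dict[str, MedianEffectFit] = {}
    for drug, (d, v) in single_drug_profiles(vt).items():
        try:
            fits[drug] = fit_median_effect(d, v, drug=drug)
        except (DegenerateFitError, InsufficientDataError):
            if on_error != "skip":
                raise
    return fits
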