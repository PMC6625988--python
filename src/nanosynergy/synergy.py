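"""Combination index and dose-reduction index against median-effect curves.

For a mixture producing fraction affected fa, each drug's equivalent
single-agent dose is Dx_j = Dm_j · (fa/(1−fa))^(1/m_j).  The Loewe-type
combination index is

    CI = Σ_j D_j / Dx_j,

and the per-drug dose-reduction index is DRI_j = Dx_j / D_j, so the duality
CI = Σ_j 1/DRI_j holds exactly.  Interactions are classified with the
screen's bands: CI < 0.8 synergistic, 0.8 ≤ CI ≤ 1 additive, CI > 1
antagonistic (boundaries map to additive); the bands are configurable.

This is the non-constant-ratio evaluation at each condition's own observed
fa — the factorial design is not a fixed-ratio dilution series, so the
constant-ratio variant cannot apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dose_response import MedianEffectFit, ViabilityTable
from .errors import ConfigError

__all__ = [
    "SynergyResult",
    "required_dose",
    "combination_index",
    "classify_interaction",
    "evaluate_screen",
    "SYNERGY_THRESHOLD",
    "ADDITIVE_UPPER",
]

SYNERGY_THRESHOLD = 0.8
ADDITIVE_UPPER = 1.0


@dataclass
class SynergyResult:
    condition_id: str
    fa_observed: float
    ci: float
    dri: dict[str, float] = field(default_factory=dict)
    label: str = ""


def required_dose(fit: MedianEffectFit, fa: float) -> float:
    """Single-agent dose producing fraction affected fa: Dm·(fa/(1−fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m_slope)


def classify_interaction(
    ci: float,
    synergy_threshold: float = SYNERGY_THRESHOLD,
    additive_upper: float = ADDITIVE_UPPER,
) -> str:
    """CI < 0.8 → synergistic; 0.8 ≤ CI ≤ 1 → additive; CI > 1 → antagonistic."""
    if ci <= 0:
        raise ValueError(f"combination index must be positive, got {ci}")
    if ci < synergy_threshold:
        return "synergistic"
    if ci <= additive_upper:
        return "additive"
    return "antagonistic"


def combination_index(
    doses: dict[str, float],
    fits: dict[str, MedianEffectFit],
    fa_observed: float,
    condition_id: str = "",
    synergy_threshold: float = SYNERGY_THRESHOLD,
    additive_upper: float = ADDITIVE_UPPER,
) -> SynergyResult:
    """CI and per-drug DRI of one dose mixture at its observed effect level."""
    if not 0.0 < fa_observed < 1.0:
        raise ValueError(f"fa_observed must lie strictly in (0, 1), got {fa_observed}")
    active = {d: x for d, x in doses.items() if x > 0}
    if not active:
        raise ValueError("at least one positive dose required")
    missing = [d for d in active if d not in fits]
    if missing:
        raise ConfigError(f"no median-effect fit for drug(s): {missing}")
    ci = 0.0
    dri: dict[str, float] = {}
    for drug, dose in active.items():
        dx = required_dose(fits[drug], fa_observed)
        dri[drug] = dx / dose
        ci += dose / dx
    return SynergyResult(
        condition_id=condition_id,
        fa_observed=fa_observed,
        ci=ci,
        dri=dri,
        label=classify_interaction(ci, synergy_threshold, additive_upper),
    )


def evaluate_screen(
    vt: ViabilityTable,
    fits: dict[str, MedianEffectFit],
    roles: tuple[str, ...] = ("mixture",),
) -> dict[str, SynergyResult]:
    """CI/DRI for every condition of the requested roles, at each condition's
    replicate-mean fa.  Conditions are skipped when their mean fa falls
    outside (0, 1) (no effect level at which to evaluate dose equivalence)
    or when a dosed drug has no single-agent fit."""
    fa_by_cond = vt.fraction_affected()
    out: dict[str, SynergyResult] = {}
    for cond in vt.design.conditions:
        if cond.role not in roles or cond.id not in fa_by_cond.index:
            continue
        if any(x > 0 and d not in fits for d, x in cond.doses.items()):
            continue
        fa = float(fa_by_cond[cond.id])
        if not 0.0 < fa < 1.0:
            continue
        out[cond.id] = combination_index(cond.doses, fits, fa, condition_id=cond.id)
    return out


def synergy_report(results: dict[str, SynergyResult]) -> pd.DataFrame:
    """Flat table: condition_id, fa, ci, label, dri_<drug> columns."""
    rows = []
    for r in results.values():
        row = {"condition_id": r.condition_id, "fa": r.fa_observed, "ci": r.ci, "label": r.label}
        for drug, v in r.dri.items():
            row[f"dri_{drug}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
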