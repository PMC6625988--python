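"""Two-stage in vitro selection via a quadratic response surface.

Stage 1 fits viability y on the full quadratic surface of the standardized
doses x_i ∈ [0, 1] (dose / per-drug max level):

    y = b0 + Σ b_i x_i + Σ b_ii x_i² + Σ_{i<j} b_ij x_i x_j + ε

with bidirectional stepwise term selection minimizing AIC (a classical
p-value enter/stay mode is available by flag).  For k drugs the candidate
matrix has 1 + k + k + k(k−1)/2 terms.  Potent effector drugs are ranked by
their retained standardized linear coefficients, most viability-reducing
(most negative) first.

Stage 2 selects, among the mixture conditions whose active drugs are
exactly the potent set, the cocktail with minimal mean viability; ties are
broken by lower combination index, then lower total standardized dose.

Dose standardization makes coefficients comparable across drugs whose raw
concentrations differ by orders of magnitude (e.g. 5-FU at hundreds of
μg/ml vs paclitaxel below 1 μg/ml).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dose_response import ViabilityTable
from .errors import InsufficientDataError, SelectionError, SingularModelError
from .synergy import SynergyResult

__all__ = [
    "RegressionModel",
    "OptimalCombination",
    "candidate_terms",
    "build_design_matrix",
    "fit_response_surface",
    "rank_effectors",
    "select_optimal_combination",
]


@dataclass
class RegressionModel:
    """Stepwise-selected quadratic response-surface fit (standardized doses)."""

    drugs: list[str]
    intercept: float
    coefficients: dict[str, float]  # retained terms only
    p_values: dict[str, float]
    included_terms: list[str]
    r_squared: float
    residual_sd: float
    aic: float
    aic_path: list[tuple[str, float]] = field(default_factory=list)

    def linear_coefficient(self, drug: str) -> float | None:
        return self.coefficients.get(drug)

    def to_report(self) -> dict:
        return {
            "drugs": self.drugs,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "p_values": {k: (None if not np.isfinite(v) else v) for k, v in self.p_values.items()},
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "aic": self.aic,
            "aic_path": self.aic_path,
        }


@dataclass
class EffectorRank:
    drug: str
    coefficient: float | None
    potent: bool


@dataclass
class OptimalCombination:
    condition_id: str
    doses: dict[str, float]
    mean_viability: float
    ci: float | None
    justification: dict = field(default_factory=dict)


def candidate_terms(drugs: list[str]) -> list[str]:
    """Canonical term order: linear, quadratic, then bilinear with i<j."""
    terms = list(drugs)
    terms += [f"{d}^2" for d in drugs]
    terms += [f"{a}:{b}" for a, b in itertools.combinations(drugs, 2)]
    return terms


def build_design_matrix(vt: ViabilityTable) -> tuple[pd.DataFrame, pd.Series]:
    """Full quadratic candidate matrix on [0,1]-standardized doses.

    One row per replicate measurement (no pre-averaging); returns (X, y)
    with X's columns in canonical term order, no intercept column.
    """
    design_df = vt.design.to_frame()
    df = vt.records.merge(design_df, on="condition_id")
    maxima = vt.design.max_levels()
    drugs = vt.design.drug_names
    X = pd.DataFrame(index=df.index)
    for d in drugs:
        denom = maxima[d] if maxima[d] > 0 else 1.0
        X[d] = df[d] / denom
    for d in drugs:
        X[f"{d}^2"] = X[d] ** 2
    for a, b in itertools.combinations(drugs, 2):
        X[f"{a}:{b}"] = X[a] * X[b]
    return X[candidate_terms(drugs)], df["viability"].rename("y")


def _aic(rss: float, n: int, k: int, floor: float) -> float:
    # own formula so that perfect (rss=0) fits stay comparable: among them the
    # smaller model wins via the 2k penalty
    return n * math.log(max(rss, floor) / n) + 2 * k


def _ols_rss(Xc: np.ndarray, y: np.ndarray) -> float | None:
    """RSS of least squares on columns Xc (with intercept); None if rank-deficient."""
    A = np.column_stack([np.ones(len(y)), Xc]) if Xc.size else np.ones((len(y), 1))
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return None
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid)


def fit_response_surface(
    vt: ViabilityTable,
    criterion: str = "aic",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    exact_max_terms: int = 10,
) -> RegressionModel:
    """Stepwise-selected OLS on the quadratic surface.

    criterion='aic' (default) returns the AIC-minimal subset: by exhaustive
    enumeration when the candidate set has at most ``exact_max_terms`` terms
    (at most 2^10 small fits — enumeration is then cheaper than worrying
    about greedy local optima), and by bidirectional greedy stepwise (apply
    the add-or-drop move that most lowers AIC until none improves) beyond.
    criterion='pvalue' alternates forward entry (smallest p < p_enter) and
    backward elimination (largest p > p_remove).  Deterministic for
    identical input, including under row permutation.
    """
    X, y = build_design_matrix(vt)
    yv = y.to_numpy(float)
    n = len(yv)
    terms = list(X.columns)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    floor = max(tss, 1.0) * 1e-14

    if criterion == "aic":
        if len(terms) <= exact_max_terms:
            included, best = _select_exhaustive(X, yv, terms, n, floor)
            path = [("+".join(included) if included else "<intercept>", best)]
        else:
            included, best, path = _select_greedy(X, yv, terms, n, floor)
        included = [t for t in terms if t in included]  # canonical order
    elif criterion == "pvalue":
        included = []
        while True:
            changed = False
            # forward: best entering term
            best_t, best_p = None, p_enter
            for t in terms:
                if t in included:
                    continue
                trial = included + [t]
                res = _sm_fit(X[trial], yv)
                if res is None:
                    continue
                p = res.pvalues.iloc[-1]
                if np.isfinite(p) and p < best_p:
                    best_t, best_p = t, p
            if best_t is not None:
                included.append(best_t)
                changed = True
            # backward: worst staying term
            if included:
                res = _sm_fit(X[included], yv)
                if res is not None:
                    pv = res.pvalues.iloc[1:]
                    worst = pv.idxmax()
                    if np.isfinite(pv[worst]) and pv[worst] > p_remove:
                        included.remove(worst)
                        changed = True
            if not changed:
                break
        included = [t for t in terms if t in included]
        path = []
    else:
        raise ValueError(f"unknown criterion '{criterion}'")

    res = _sm_fit(X[included], yv)
    if res is None:
        raise SingularModelError("final model is rank-deficient", terms=included)
    params = res.params
    rss = float(res.ssr)
    k = len(included) + 1
    resid_sd = math.sqrt(rss / max(n - k, 1))
    coeffs = {t: float(params[t]) for t in included}
    pvals = {t: float(res.pvalues[t]) for t in included}
    return RegressionModel(
        drugs=vt.design.drug_names,
        intercept=float(params["const"]),
        coefficients=coeffs,
        p_values=pvals,
        included_terms=included,
        r_squared=float(res.rsquared) if np.isfinite(res.rsquared) else 1.0,
        residual_sd=resid_sd,
        aic=_aic(rss, n, k, floor),
        aic_path=path if criterion == "aic" else [],
    )


def _select_exhaustive(X, yv, terms, n, floor):
    """AIC-minimal subset by enumeration; first-found wins exact ties
    (subsets enumerated by size then canonical term order, so the smaller
    model is preferred deterministically)."""
    best_sub, best_aic = [], _aic(_ols_rss(np.empty((n, 0)), yv), n, 1, floor)
    for r in range(1, len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            rss = _ols_rss(X[list(sub)].to_numpy(float), yv)
            if rss is None:
                continue
            a = _aic(rss, n, r + 1, floor)
            if a < best_aic - 1e-10:
                best_sub, best_aic = list(sub), a
    return best_sub, best_aic


def _select_greedy(X, yv, terms, n, floor):
    included: list[str] = []
    best = _aic(_ols_rss(np.empty((n, 0)), yv), n, 1, floor)
    path: list[tuple[str, float]] = [("<intercept>", best)]
    while True:
        best_move, best_candidate_aic = None, best
        for t in terms:
            trial = included + [t] if t not in included else [u for u in included if u != t]
            rss = _ols_rss(X[trial].to_numpy(float), yv)
            if rss is None:
                continue
            a = _aic(rss, n, len(trial) + 1, floor)
            if a < best_candidate_aic - 1e-10:
                best_move, best_candidate_aic = trial, a
        if best_move is None:
            break
        included, best = best_move, best_candidate_aic
        path.append(("+".join(included) if included else "<intercept>", best))
    return included, best, path


def _sm_fit(Xdf: pd.DataFrame, y: np.ndarray):
    A = sm.add_constant(Xdf.to_numpy(float) if len(Xdf.columns) else np.empty((len(y), 0)), has_constant="add")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return None
    res = sm.OLS(y, A).fit()
    res.params = pd.Series(res.params, index=["const"] + list(Xdf.columns))
    res.pvalues = pd.Series(res.pvalues, index=["const"] + list(Xdf.columns))
    return res


def rank_effectors(model: RegressionModel, alpha: float | None = 0.05) -> list[EffectorRank]:
    """Order drugs by viability-reducing potency.

    Potent = retained linear term with a negative coefficient (and, when
    ``alpha`` is given, p < alpha; non-finite p-values from saturated
    noise-free fits pass on sign alone).  Potent drugs come first, most
    negative coefficient first; non-potent drugs follow in design order,
    flagged.  Equal coefficients keep design order (stable sort).
    """
    if not any(d in model.coefficients for d in model.drugs):
        raise InsufficientDataError("no retained linear term; cannot rank effectors")
    potent, rest = [], []
    for d in model.drugs:
        coef = model.coefficients.get(d)
        if coef is None or coef >= 0:
            rest.append(EffectorRank(d, coef, False))
            continue
        p = model.p_values.get(d, float("nan"))
        if alpha is not None and np.isfinite(p) and p >= alpha:
            rest.append(EffectorRank(d, coef, False))
            continue
        potent.append(EffectorRank(d, coef, True))
    potent.sort(key=lambda e: e.coefficient)  # stable: ties keep design order
    return potent + rest


def select_optimal_combination(
    vt: ViabilityTable,
    potent: list[str],
    synergy: dict[str, SynergyResult] | None = None,
    require_ci: bool = False,
) -> OptimalCombination:
    """Minimal-mean-viability cocktail over mixtures of exactly the potent set.

    Ties break by lower CI (when synergy results are supplied), then by
    lower total standardized dose.  With ``require_ci`` only cocktails with
    an evaluable combination index are eligible — saturated conditions
    (every replicate at 0% viability, fa = 1) have no effect level at which
    dose equivalence, hence DRI, can be computed.
    """
    potent_set = set(potent)
    if not potent_set:
        raise SelectionError("empty potent-drug set")
    mean_v = vt.mean_viability()
    maxima = vt.design.max_levels()
    candidates = []
    for cond in vt.design.conditions:
        if cond.role != "mixture" or cond.id not in mean_v.index:
            continue
        active = {d for d, x in cond.doses.items() if x > 0}
        if active != potent_set:
            continue
        ci = None
        if synergy is not None and cond.id in synergy:
            ci = synergy[cond.id].ci
        if require_ci and ci is None:
            continue
        std_total = sum(x / maxima[d] for d, x in cond.doses.items() if x > 0)
        candidates.append((float(mean_v[cond.id]), ci, std_total, cond))
    if not candidates:
        raise SelectionError(f"no mixture condition uses exactly the potent set {sorted(potent_set)}")
    candidates.sort(key=lambda t: (t[0], t[1] if t[1] is not None else float("inf"), t[2]))
    v, ci, std_total, cond = candidates[0]
    return OptimalCombination(
        condition_id=cond.id,
        doses={d: x for d, x in cond.doses.items() if x > 0},
        mean_viability=v,
        ci=ci,
        justification={
            "potent_drugs": sorted(potent_set),
            "n_candidates": len(candidates),
            "total_standardized_dose": std_total,
        },
    )
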