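import itertools
import math

import numpy as np
import pandas as pd
import pytest

import nanosynergy as ns
from nanosynergy.errors import SelectionError
from nanosynergy.screening import (
    EffectorRank,
    RegressionModel,
    build_design_matrix,
    candidate_terms,
    fit_response_surface,
    rank_effectors,
    select_optimal_combination,
)
from nanosynergy.synergy import SynergyResult


def two_drug_design(levels=(0.0, 1.0, 2.0)):
    return ns.build_factorial_design([ns.DrugSpec("A", levels), ns.DrugSpec("B", levels)])


def table_from_truth(design, fn, reps=1, noise_sd=0.0, seed=0):
    """Viability from a function of the standardized doses, plus noise."""
    rng = np.random.default_rng(seed)
    maxima = design.max_levels()
    rows = []
    for cond in design.conditions:
        x = {d: cond.doses[d] / maxima[d] for d in design.drug_names}
        v = fn(x)
        for rep in range(1, reps + 1):
            rows.append({
                "condition_id": cond.id, "replicate": rep,
                "viability": max(0.0, v + (rng.normal(0, noise_sd) if noise_sd else 0.0)),
            })
    return ns.ViabilityTable(records=pd.DataFrame(rows), design=design)


def exhaustive_best_subset(X, y):
    """Independent oracle: enumerate every subset, pick minimal AIC."""
    yv = np.asarray(y, float)
    n = len(yv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    floor = max(tss, 1.0) * 1e-14
    best, best_aic = set(), None
    for r in range(len(X.columns) + 1):
        for sub in itertools.combinations(X.columns, r):
            A = np.column_stack([np.ones(n)] + [X[t].to_numpy(float) for t in sub])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                continue
            coef, _, _, _ = np.linalg.lstsq(A, yv, rcond=None)
            rss = float(np.sum((yv - A @ coef) ** 2))
            aic = n * math.log(max(rss, floor) / n) + 2 * (r + 1)
            if best_aic is None or aic < best_aic - 1e-10:
                best, best_aic = set(sub), aic
    return best


class TestResponseSurface:
    def test_candidate_term_count_is_quadratic_in_drug_count(self):
        for k in (2, 3, 4):
            assert len(candidate_terms([f"D{i}" for i in range(k)])) == 2 * k + k * (k - 1) // 2
        assert 1 + len(candidate_terms(list("ABCD"))) == 15

    def test_planted_single_linear_term_retained_alone(self):
        vt = table_from_truth(two_drug_design(), lambda x: 100 - 30 * x["A"], reps=2)
        model = fit_response_surface(vt)
        assert model.included_terms == ["A"]
        assert model.coefficients["A"] == pytest.approx(-30.0, abs=1e-9)
        assert model.intercept == pytest.approx(100.0, abs=1e-9)

    def test_planted_full_quadratic_recovered_to_machine_precision(self):
        truth = lambda x: 90 - 25 * x["A"] - 12 * x["B"] + 6 * x["A"] ** 2 - 9 * x["B"] ** 2 - 14 * x["A"] * x["B"]
        vt = table_from_truth(two_drug_design(), truth, reps=2)
        model = fit_response_surface(vt)
        assert set(model.included_terms) == {"A", "B", "A^2", "B^2", "A:B"}
        expected = {"A": -25, "B": -12, "A^2": 6, "B^2": -9, "A:B": -14}
        for term, val in expected.items():
            assert model.coefficients[term] == pytest.approx(val, abs=1e-8)

    @pytest.mark.parametrize("seed", range(12))
    def test_selection_matches_exhaustive_best_subset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coefs = rng.normal(0, 30, 5) * rng.binomial(1, 0.5, 5)

        def truth(x):
            return (100 + coefs[0] * x["A"] + coefs[1] * x["B"]
                    + coefs[2] * x["A"] ** 2 + coefs[3] * x["B"] ** 2
                    + coefs[4] * x["A"] * x["B"])

        vt = table_from_truth(two_drug_design(), truth, reps=2, noise_sd=3.0, seed=seed + 100)
        model = fit_response_surface(vt)
        X, y = build_design_matrix(vt)
        assert set(model.included_terms) == exhaustive_best_subset(X, y)

    def test_row_permutation_invariance(self, synergistic_screen):
        model = fit_response_surface(synergistic_screen)
        shuffled = ns.ViabilityTable(
            records=synergistic_screen.records.sample(frac=1.0, random_state=9).reset_index(drop=True),
            design=synergistic_screen.design,
        )
        model2 = fit_response_surface(shuffled)
        assert model.included_terms == model2.included_terms
        for t in model.included_terms:
            assert model.coefficients[t] == pytest.approx(model2.coefficients[t], rel=1e-9)

    def test_pvalue_mode_finds_planted_term(self):
        vt = table_from_truth(two_drug_design(), lambda x: 100 - 40 * x["A"], reps=3, noise_sd=2.0, seed=1)
        model = fit_response_surface(vt, criterion="pvalue")
        assert "A" in model.included_terms
        assert model.coefficients["A"] < -30


def model_with(coefs, drugs=None, pvals=None):
    drugs = drugs or list(coefs)
    return RegressionModel(
        drugs=drugs, intercept=100.0, coefficients=dict(coefs),
        p_values=pvals or {d: 0.001 for d in coefs}, included_terms=list(coefs),
        r_squared=0.9, residual_sd=1.0, aic=0.0,
    )


class TestRankEffectors:
    def test_orders_by_most_negative_and_flags_nonnegative(self):
        ranked = rank_effectors(model_with({"A": -30.0, "B": -5.0, "C": 2.0}))
        assert [e.drug for e in ranked] == ["A", "B", "C"]
        assert [e.potent for e in ranked] == [True, True, False]

    def test_near_null_drug_excluded_from_top_three(self, four_drug_design, true_params):
        # 5-FU's tested doses sit far below its Dm: planted near-zero effect
        cfg = ns.ScreenSimConfig(
            design=four_drug_design, true_params=true_params,
            interaction_gamma=1.0, replicates=1, noise_sd=0.0, seed=3,
        )
        vt = ns.simulate_screen(cfg)
        ranked = rank_effectors(fit_response_surface(vt))
        top3 = [e.drug for e in ranked if e.potent][:3]
        assert "5-FU" not in top3
        assert set(top3) == {"cisplatin", "paclitaxel", "doxorubicin"}

    def test_equal_coefficients_keep_drug_order(self):
        ranked = rank_effectors(model_with({"A": -10.0, "B": -10.0, "C": -10.0}))
        assert [e.drug for e in ranked] == ["A", "B", "C"]

    def test_unretained_drug_ranked_last(self):
        m = model_with({"A": -10.0}, drugs=["A", "B"])
        ranked = rank_effectors(m)
        assert ranked[-1] == EffectorRank("B", None, False)


class TestSelectOptimal:
    def synergy_for(self, vt, ci_by_cond):
        return {
            cid: SynergyResult(condition_id=cid, fa_observed=0.5, ci=ci, dri={}, label="")
            for cid, ci in ci_by_cond.items()
        }

    def test_lowest_mean_viability_wins(self, synergistic_screen):
        fits = ns.fit_all_single_drugs(synergistic_screen)
        results = ns.evaluate_screen(synergistic_screen, fits)
        best = select_optimal_combination(
            synergistic_screen, ["cisplatin", "paclitaxel", "doxorubicin"], results
        )
        mean_v = synergistic_screen.mean_viability()
        eligible = [
            c.id for c in synergistic_screen.design.conditions
            if c.role == "mixture"
            and {d for d, x in c.doses.items() if x > 0} == {"cisplatin", "paclitaxel", "doxorubicin"}
        ]
        assert len(eligible) == 8  # 2^3 dose choices for the 3 drugs
        assert best.condition_id == min(eligible, key=lambda cid: mean_v[cid])
        assert best.mean_viability == pytest.approx(mean_v[eligible].min())

    def test_tie_broken_by_lower_ci(self):
        design = ns.build_factorial_design(
            [ns.DrugSpec("A", (0.0, 1.0, 2.0)), ns.DrugSpec("B", (0.0, 1.0))]
        )
        rows = []
        for cond in design.conditions:
            v = 40.0 if cond.role == "mixture" else 100.0
            rows.append({"condition_id": cond.id, "replicate": 1, "viability": v})
        vt = ns.ViabilityTable(records=pd.DataFrame(rows), design=design)
        mixtures = [c.id for c in design.conditions if c.role == "mixture"]
        assert len(mixtures) == 2
        syn = self.synergy_for(vt, {mixtures[0]: 0.9, mixtures[1]: 0.3})
        best = select_optimal_combination(vt, ["A", "B"], syn)
        assert best.condition_id == mixtures[1]

    def test_single_eligible_cocktail_returned(self):
        design = ns.build_factorial_design(
            [ns.DrugSpec("A", (0.0, 1.0)), ns.DrugSpec("B", (0.0, 1.0))]
        )
        rows = [{"condition_id": c.id, "replicate": 1, "viability": 95.0} for c in design.conditions]
        vt = ns.ViabilityTable(records=pd.DataFrame(rows), design=design)
        best = select_optimal_combination(vt, ["A", "B"], None)
        assert best.mean_viability == 95.0

    def test_no_eligible_cocktail_raises(self, synergistic_screen):
        with pytest.raises(SelectionError):
            select_optimal_combination(synergistic_screen, ["cisplatin"], None)
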