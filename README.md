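# nanosynergy

Analysis pipeline for miniaturized drug-combination screens: factorial
combination design, dose–response and median-effect fitting, Chou–Talalay
combination-index synergy scoring, two-stage optimal-cocktail selection via
a quadratic response surface, translation of the selected in vitro
combination into in vivo dose ranges, and xenograft growth-curve
evaluation. A synthetic-data module generates screens and tumor datasets
with the statistical structure the analysis assumes, so the whole chain is
testable without instrument data.

The package is aimed at screening labs that run small-volume (nanodroplet
or plate) viability assays over full factorials of drug doses — e.g. four
chemotherapeutics at three levels each, 3⁴ = 81 conditions with ~100 cells
per 200-nl droplet — and need a reproducible path from raw viability tables
to a ranked, synergy-checked cocktail and a mouse dosing plan.

## The models at the core

**Median-effect dose–response.** Each drug alone follows
fa/fu = (D/Dm)^m, with fa the fraction affected (1 − viability/100),
fu = 1 − fa, Dm the median-effect dose and m the sigmoidicity. The fit is
ordinary least squares of log₁₀(fa/fu) on log₁₀ D. A four-parameter
logistic v(D) = d + (a−d)/(1 + (D/c)^b) is fitted alongside; when the
asymptotes span 100 → 0 its inflection dose c is the IC50 and coincides
with Dm.

**Combination index and dose-reduction index.** For a mixture producing
effect fa, each drug's equivalent single-agent dose is
Dx_j = Dm_j·(fa/fu)^(1/m_j), and

    CI  = Σ_j D_j / Dx_j,      DRI_j = Dx_j / D_j,      CI = Σ_j 1/DRI_j.

CI < 0.8 is called synergistic, 0.8 ≤ CI ≤ 1 additive, CI > 1 antagonistic
(configurable thresholds).

**Two-stage selection.** Stage 1 fits viability on the full quadratic
response surface of the [0,1]-standardized doses,
y = b₀ + Σb_i·x_i + Σb_ii·x_i² + Σ_{i<j} b_ij·x_i·x_j + ε, with
AIC-minimal term selection, and ranks drugs by their retained linear
coefficients (most viability-reducing first). Stage 2 picks, among mixtures
of exactly the top-k potent drugs, the one with minimal mean viability
(ties: lower CI, then lower total standardized dose).

**In vitro → in vivo translation.** With DRI_ave the arithmetic mean of the
cocktail's per-drug DRIs and n the number of administrations,

    D_invivo = (MTD / DRI_ave) × n    per drug, per administration,

capped at the drug's own maximum tolerated dose (MTD).

**Xenografts.** Tumor volume from two orthogonal caliper diameters,
V = (π/6)(a·b)^{3/2}; growth as percent volume change against day 0;
group comparisons by t-test / one-way ANOVA / two-way (group × day) ANOVA;
a noncentral-t power calculator for cohort sizing.

## Worked example

`examples/dose_translation.py` translates the screen-derived dose-reduction
indices of the optimal cisplatin/paclitaxel/doxorubicin cocktail into mouse
dose ranges:

```
DRI_ave = 28.3667 (reported as 28.4)
  cisplatin      1.0-  1.6 mg/kg  [within MTD]
  paclitaxel     3.7-  8.9 mg/kg  [within MTD]
  doxorubicin    0.5-  2.5 mg/kg  [within MTD]
```

The three drugs can be dosed on average 28.4-fold below their single-agent
requirements, so spreading each MTD over the 7-injection course yields
per-injection windows of 1.0–1.6, 3.7–8.9 and 0.5–2.5 mg/kg — all safely
under the respective MTDs.

`examples/screen_to_cocktail.py` runs the whole in vitro chain on a
simulated screen with a planted Loewe interaction γ = 0.5:

```
72 mixtures: CI = 0.500 +/- 8.8e-14 (planted gamma = 0.5 recovered)
...
optimal cocktail C075: {'cisplatin': 10.0, 'paclitaxel': 1.2, 'doxorubicin': 20.0}
  mean viability 9.9%  CI 0.50 (synergistic)
```

The recovered CI equals the planted interaction exactly on noise-free data
because the generator and the analysis share the Loewe/median-effect
identity — that round trip is the package's core correctness check.

The other examples cover the factorial design itself
(`factorial_design.py`) and the xenograft analysis
(`xenograft_analysis.py`). A thin CLI exposes the same stages
(`nanosynergy design | simulate-screen | fit-dr | synergy | screen |
translate | simulate-tumors | invivo | all`).

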