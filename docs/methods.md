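# Methods

This note documents the models, numerical choices and limitations behind
each pipeline stage, and what the synthetic-data generator does and does
not emulate.

## Factorial design

A screen is defined by drugs with strictly increasing dose ladders whose
first level is exactly 0. The zero level is mandatory: the untreated
control and the single-drug conditions only exist as factorial cells if
every drug has an "absent" level, so this is enforced rather than
inferred. Conditions are the full Cartesian product, ordered
lexicographically by drug-list order then ascending level index; ids are
zero-padded (`C001`…). The ordering carries no experimental meaning — the
physical well-to-condition assignment of a real chip is not modeled — but
determinism makes every downstream artifact byte-reproducible. Plate
assignment is row-major onto the first N cells; no randomization, blocking
or edge-effect modeling is attempted.

Two chip-level descriptive utilities live here as well: the coefficient of
variation of well diameters (100·sd/mean) and the assay miniaturization
factor (conventional well volume / droplet volume, e.g. 100 μl vs 200 nl
→ 500).

## Synthetic screens

Single-drug effects follow the median-effect model
fa/(1−fa) = (D/Dm)^m. Mixture effects are generated from the
combination-index identity itself: fa solves

    Σ_j D_j / [Dm_j (fa/(1−fa))^(1/m_j)] = γ

by Brent's method on fa ∈ (10⁻⁹, 1−10⁻⁹); the left side is strictly
decreasing in fa, so the root is unique and always bracketed for positive
doses. γ = 1 is Loewe additivity, γ < 1 planted synergy, γ > 1 planted
antagonism. Because generator and analysis share this identity, a correct
analysis recovers CI = γ exactly on noise-free data — this round trip is
the pipeline's strongest self-check, and it is why the Loewe generator is
the default (a Bliss-independence alternative exists behind a flag but
breaks the exact round trip by construction).

Noise is additive Gaussian on percent viability, truncated below at 0 and
deliberately **not** clamped at 100, so the control mean stays unbiased and
testable. Per droplet, the noise sd is inflated by √(mean_cells/actual)
with actual ~ Poisson(mean_cells = 100), encoding the counting statistics
of seeding ~100 cells in 200 nl; empty-droplet draws are resampled. The
default noise_sd = 5 percentage points is a fixture choice — no assay
noise magnitude is published for this platform — sized so that replicate
scatter resembles small-volume viability assays.

A dedicated single-agent titration generator (8 log-spaced doses spanning
1/30×–30× the drug's active range, same noise model) complements the
factorial screen: a screen with only two positive levels per drug cannot
anchor a stable median-effect fit for a weak drug under noise, which is
also why real screens pair a combination matrix with separate IC50
titrations.

Tumors grow as V(t) = V₀·exp[(growth − inhibition)·t] with V₀ = 100 mm³
and are reported as two orthogonal diameters around l = (6V/π)^(1/3) with
Gaussian caliper noise (sd 0.3 mm; negative draws resampled). Default
schedule: days 0, 3, 5, 7, 9, 11, 13, 15. The exponential-with-constant-
inhibition law is the simplest model consistent with two-week growth
curves; no pharmacokinetics, regrowth or heterogeneity is modeled, so
passing tests show correct *analysis* of such data, not realism of any
particular tumor model.

## Dose–response fitting

Raw intensities are normalized to percent of the untreated-control mean
(control mean ≡ 100%); the operation is idempotent on already-normalized
tables. The 4PL fit is unweighted least squares via trust-region
optimization, initialized at a = max response, d = min response,
c = geometric mean of positive doses, b = 1, with c bounded positive;
non-convergence is flagged on the result, and a flat response raises a
degenerate-fit error. At least 4 distinct positive doses are required.

The median-effect fit is OLS of log₁₀(fa/fu) on log₁₀ D (base-10
throughout, the field's convention). Points with D = 0 or fa outside the
open interval (0, 1) are **dropped, not clipped** — clipping biases the
logit — and the dropped count is surfaced. Replicates enter pooled as
separate points rather than dose-averaged, preserving the error structure.
A non-positive fitted slope (no dose signal) is a degenerate fit; the
screen-level wrapper can skip such drugs instead of aborting, since
mixtures not involving them remain analyzable.

## Synergy scoring

CI and DRI are evaluated non-constant-ratio, at each condition's own
replicate-mean fa — the factorial design is not a fixed-ratio dilution
series, so the constant-ratio variant cannot apply. The duality
CI = Σ 1/DRI holds to machine precision by construction. Classification
bands: CI < 0.8 synergistic, 0.8 ≤ CI ≤ 1 additive (both boundaries
additive), CI > 1 antagonistic; the 0.8 synergy bound is stricter than the
conventional 1.0 and is kept configurable. Conditions whose mean fa
reaches 0 or 1 (untouched or saturated wells) have no effect level at
which dose equivalence is defined and are skipped with that reason.

## Response-surface screening

The stage-1 model is the full quadratic surface on doses standardized to
[0, 1] by each drug's maximum tested level — without standardization the
coefficients of drugs dosed 1000× apart (5-fluorouracil vs paclitaxel) are
incomparable. For k drugs there are 2k + k(k−1)/2 candidate terms plus the
intercept (15 for k = 4).

Term selection minimizes AIC computed as n·log(max(RSS, ε)/n) + 2k with a
tiny RSS floor (10⁻¹⁴ of the total sum of squares): the floor keeps
saturated noise-free fits comparable, so among perfect fits the smaller
model wins deterministically. When the candidate set has ≤ 10 terms the
AIC-optimal subset is found by exhaustive enumeration (≤ 1024 small OLS
fits — measurably, greedy stepwise lands in a local optimum on a few
percent of random sparse-signal datasets, and enumeration at this size
costs nothing); larger candidate sets use bidirectional greedy stepwise
(apply the add-or-drop move that most lowers AIC until none improves). A
classical p-value mode (enter 0.05 / stay 0.10) is available by flag.
Selection is invariant to row order; rank-deficient candidate models are
skipped and a rank-deficient final model is an error naming its terms.

"Potent effector" means a retained linear term with a negative
coefficient, additionally required to be significant at α = 0.05 when a
finite p-value exists (saturated noise-free fits have zero residual
variance and degenerate p-values, which pass on sign alone). Potent drugs
rank by ascending coefficient; ties and non-potent drugs keep design
order. The top-k (default 3) feed stage 2, which selects the
minimal-mean-viability mixture using exactly that drug set, breaking ties
by lower CI then lower total standardized dose. An optional `require_ci`
flag restricts stage 2 to cocktails with an evaluable CI, which the CLI
chain uses so that translation always has DRIs to work from.

## Dose translation

DRI_ave is the arithmetic mean over the cocktail's drugs — m in the
denominator, not the administration count: only this reading reproduces
the worked averages 28.4 = (45.4+34.4+5.3)/3 and 9.2 = (5.1+18.6+4.0)/3.
DRI_ave is kept unrounded inside the arithmetic; rounding it first to 9.2
would shift the paclitaxel upper endpoint from 27.3 to 27.4 mg/kg. Report
values round half-away-from-zero to one decimal, with raw values emitted
alongside. The MTD constraint (translated dose ≤ MTD upper bound,
inclusive) is checked per drug; the module reports ranges and flags and
never picks a single dose within a range — that margin choice is left to
the experimenter. No animal-to-human body-surface-area conversion is
attempted.

## Xenograft evaluation

V = (π/6)(a·b)^{3/2} from the two orthogonal diameters (equivalently
(4π/3)(l/2)³ with l = √(ab)). Percent change is per mouse against its own
day-0 volume; mice without a day-0 record are excluded with a warning
(animals lost mid-study keep their records up to the last observation).
Group means can be renormalized so the control group's final-day mean
reads 100%. Comparisons: two-sample t (two groups, one day), one-way
ANOVA (> 2 groups, one day), and fixed-effects two-way ANOVA (group × day)
with Type II sums of squares, which reduce to the classical balanced
decomposition on balanced data and tolerate the mild imbalance of lost
animals; significance at p < 0.05. The power calculator inverts the
noncentral-t power function (noncentrality effect·√(n/2), df 2n−2) by
searching the smallest integer n; it reproduces the standard benchmark
n = 17 per group at effect 1.0, α = 0.05, power 0.8.

## Problem sizes and test design

The test-suite simulations use the design sizes the method targets: the
81-condition screen at 1–3 replicates, 200-replicate parameter-recovery
and effector-ranking batches on 27–81-condition designs, and 4-mouse
groups over the 8-day schedule. The whole suite runs in about a minute on
one CPU.

## Known limitations

- The published chip IC50s, CI values (0.2/0.5) and tumor curves cannot be
  recomputed: their raw data exist only as figures. They are replaced by
  parameter-recovery and round-trip properties on synthetic data.
- The CI round trip is exact only because generator and analysis share the
  Loewe identity; it validates the implementation, not the biology of any
  real mixture.
- Percent-viability noise is homoscedastic apart from the droplet
  cell-count inflation; real fluorescence noise is typically
  intensity-dependent.
- The unweighted logit fit attenuates the median-effect slope m under
  heavy noise (extreme-fa points are noisiest and are dropped when they
  leave (0, 1)); Dm, the quantity the CI computation actually needs, stays
  stable.
- The two-way ANOVA treats repeated measures on the same mouse as
  independent; no mixed-effects longitudinal model is provided.
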