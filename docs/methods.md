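# Methods

## Overview

`porkfresh` implements a four-stage chemometric cascade for pork-loin
freshness prediction together with a synthetic data generator that
stands in for the (undeposited) laboratory measurements. This note
records the models, the parameter choices and their rationale, the
numerical conventions, and — importantly — what the synthetic
experiments do and do not demonstrate about real data.

## Study design and generator

The default `StudyDesign` is a refrigerated-storage trial: vacuum-packed
loin from 3 animals × 2 sides, sampled on storage days {1, 4, 13, 20,
27}, with 5 chemistry replicates per day (n = 25 metabolite/quality
rows) and 4 hyperspectral observations per replicate (n = 100 spectra).
Animal and side are carried as metadata only; no random effects are
modelled because none of the downstream models use them. Quality values
are replicated across the four observations of a replicate, since each
spectral observation is matched to the chemistry of the same cut.

### Metabolites

Each of the 64 panel metabolites follows a `TrendSpec`: concentration
mean = baseline + signed effect × storage progress (progress is the day
rescaled to [0, 1]), plus Gaussian replicate noise, clipped at zero.
The census is 36 increasing, 4 decreasing (glycine, isoleucine,
niacinamide, valine) and 24 flat. Non-equation baselines and effects are
drawn once from a fixed internal stream so the default panel never
varies between runs.

The four equation metabolites have fixed trajectories chosen so the
computed indicators span realistic meat ranges and cross the spoilage
thresholds near the end of storage: lysine 2→15, malate 1→8, methionine
2→12, niacinamide 4→1 mg/dL. Their replicate noise (2.1, 1.15, 2.45,
0.75 mg/dL) is set so each within-equation pair reproduces the reference
collinearity regime at n = 25 — pair VIF near 3.4 for lysine/malate and
near 2.0 for methionine/niacinamide — because the behaviour of stepwise
selection under the VIF/CI gate depends directly on that correlation
level. A fully day-driven generator (noise ≪ trend) would push pairwise
correlations above 0.95 and the gate would reject the true models, which
is not the regime the reference diagnostics describe.

### Quality traits

TBC and VBN are computed from the reference linear equations on the
generated metabolites plus Gaussian noise (sd 0.30 log CFU/g and 0.85
mg/100 g; compatible with calibration RMSEs well under the trait spread).
pH and CIE L\*/a\*/b\* carry only weak metabolite loadings under large
noise (e.g. pH = 5.85 + 0.012·lactate − 0.005·glutamate + N(0, 0.18)),
so they are intentionally hard to predict from the panel. The VBN
reference equation is the methionine/niacinamide form; freshness
reports also circulate a methionine/histidine variant, and the two are
not reconciled here — the implemented equation is stated explicitly
wherever it is used.

A `vbn_titration` helper implements the Conway micro-diffusion
arithmetic, VBN = 0.14 × (V1 − V0) × 10 × 100 / sample mass, used as the
physical definition behind the VBN scale.

### Spectra

640 bands uniform on 278–1,724 nm. Clean reflectance = a smooth baseline
curve + Σ Gaussian signatures, each signature tied to one variable
(metabolite, quality trait, or a per-spectrum latent nuisance factor
drawn as N(1, latent_sd)). Default signatures anchor the equation
metabolites at freshness-informative wavelengths (460/540 nm visible;
721, 947, 1,214, 1,271, 1,441–1,599 nm) and add broad moisture/fat
nuisance bands. Each spectrum is then distorted by a multiplicative
scatter factor N(1, 0.08), an additive tilted baseline (offset sd 0.02,
slope sd 2·10⁻⁵ per nm) and white sensor noise (sd 0.004 reflectance
units) — so SNV/MSC are non-trivially useful. Raw scans are constructed
as S = D + R·(W − D) with constant dark/white frames, making
`calibrate_reflectance` exact by construction; out-of-[0, 1] reflectance
is retained (clipping would distort SNV/MSC) and only counted in a
warning.

All generator randomness flows through per-stage streams derived from
one seed; fixing the seed fixes every output bit-for-bit.

## Preprocessing

* **Trim** to 400–1,600 nm (fixed-range trim; an outlier-band criterion
  is deliberately not modelled).
* **SNV**: per-row centering and scaling by the n−1 sample sd (the
  denominator choice changes values by a constant factor, hence
  documented).
* **Normalization**: unit Euclidean row norm (the common toolbox
  default among the several transforms that share this name).
* **MSC**: per-row least-squares fit x ≈ a + b·ref and inversion
  (x − a)/b; the reference is the calibration-set column mean, frozen on
  the `PreprocessingTag` and reused for prediction data so no
  information flows backwards across the split. Rows with |b| below
  10⁻¹² are left intercept-centered and flagged.

## Chemometrics

* **Augmentation** (`mc_augment`): each augmented row is one uniformly
  drawn base row — all blocks drawn jointly so the metabolite/quality/
  spectrum pairing survives — plus independent Gaussian jitter per
  variable with sd = α × that variable's within-storage-day sample sd
  (α default 0.05; α = 0 is a pure bootstrap). Exactly `n_target` rows.
* **Split**: seeded shuffle, calibration size = round(0.7·n). A
  group-aware variant keeps all augmented descendants of a base row on
  one side.
* **Cross-validation**: venetian blinds, fold of sample i = i mod 10.
  "10 splits with one sample per blind" is interpreted as interleaving
  with blind thickness 1.
* **PLSR**: NIPALS with unit-norm weights; PLS1 is the exact one-pass
  solution, PLS2 iterates to tolerance 10⁻¹². X (and Y) are
  mean-centered; autoscaling is the default for metabolite-X models
  (matching how such panels are conventionally scaled) and
  centering-only for spectral-X models. Per-truncation coefficients come
  from the rotation R = W(PᵀW)⁻¹, so latent-variable selection costs one
  fit per fold; the count with the lowest RMSECV wins, ties toward fewer
  components; an infeasibly large request is capped with a warning.
* **Metrics**: RMSE and R² = 1 − SSE/SST with SST about the evaluated
  set's own mean (not squared correlation; the two differ on prediction
  sets). R²CV is derived from the RMSECV at the chosen component count.
* **VIP**: Wold's formula with SSY_a = (t_aᵀt_a)(q_aᵀq_a); Σ VIP² = p
  identically. The discriminant variant dummy-codes classes and sums SSY
  over the indicator responses; whether every external tool weights SSY
  identically is not verifiable, so both variants implement the same
  formula and are labelled as such.
* **Pattern correlations**: plain Pearson r per metabolite, sorted by
  |r|; zero-variance metabolites yield NaN.

## Stepwise regression and the collinearity gate

Forward entry by smallest partial-F p-value (enter if ≤ 0.05), backward
removal (remove if ≥ 0.10), iterated to convergence — the classic
statistical-package defaults, assumed because only "stepwise" is
specified. After convergence the gate is applied: accept iff every
VIF < 10 (strict) and every condition index < 15 (strict). Condition
indices follow the convention of scaling each column of the
intercept-augmented, *uncentered* design to unit Euclidean length and
taking √(λ_max/λ_k) of the cross-product eigenvalues, so the leading
index is exactly 1; centered variants give different numbers and are not
used. If the gate fails, the most recently entered violating term is
removed (and barred) and selection resumes — the gate is a model-choice
criterion, so enforcement is post-convergence with backtracking rather
than inside the entry test. An empty model returns intercept-only with
`accepted = False`.

## Cascade order of operations

Generation → trim → pairing (chemistry replicated over observations) →
augmentation → one shared 7:3 split → preprocessing fit on calibration
only → per-target LV selection and fit. Preprocessing after
augmentation/split avoids one leakage channel while keeping the
augment-first structure. The freshness equations are fit on the
unaugmented n = 25 chemistry rows. Model 4 consumes, per indicator, the
Model-2 winning predictions of that indicator's equation metabolites on
the shared prediction set, stacks them beside the (re-preprocessed)
spectra of those rows, re-splits 7:3 and fits; Y is the measured
indicator by default (`model4_y_source="model3"` substitutes the
Model-3 predictions). The stacked metabolite columns are not rescaled by
default: their natural mg/dL variance dominates the centered spectral
block, which is precisely what makes them act as distilled features; an
autoscale switch exists. Model 4's rows are all drawn from the shared
prediction set, never from the Model-2/3 calibration rows (asserted by
sample-id provenance).

## What the synthetic experiments show — and what they don't

**Leakage and the augment-then-split protocol.** Augmenting 100 paired
rows to 10,000 and then splitting row-wise places descendants of the
same base row on both sides of the split. With 64 metabolite predictors
against 25 distinct chemistry rows (or 531 bands against 100 spectra), a
linear model with enough latent variables can nearly interpolate the
base-row values, so absolute R²P values under the replicated protocol
are optimistic for *every* trait (≈ 0.99 at large LV counts). The
protocol is replicated deliberately; the *ordering* of traits — TBC and
VBN best-predicted, pH/color worst — survives, because the ranking is
driven by each trait's within-day noise share. The group-aware split
reduces but does not remove the effect (sibling observations of a
replicate still share chemistry). Consequently, absolute R² values from
this pipeline's default protocol should not be read as honest
generalization estimates — on synthetic or on real data.

**Combination-model experiment.** In a linear world the Model-4 feature
set (spectra plus linear functions of spectra) adds no information, so
any genuine advantage must come from estimation geometry: the stacked
columns concentrate the indicator-relevant contrast into two
high-variance directions that PLSR captures within 1–2 components,
whereas the spectra-only model must assemble the same contrast from many
bands against nuisance variance. This advantage is therefore visible
exactly in the regime the reference models occupied — few latent
variables (2–4) and strong indicator-independent spectral nuisance. The
packaged experiment (`porkfresh.experiments.combination_experiment`)
runs at max 3 LVs with overlapping moisture/fat/myoglobin nuisance
bands (latent sd 1.2, sensor noise 0.04) and n = 2,000–3,000
augmentation; Model 4 then beats Model 3 in roughly 80% of paired
seeds with mean ΔR²P ≈ +0.04, and replacing the stacked columns with
matched-variance noise collapses the gain to below zero. At large LV
budgets both models saturate and the delta disappears — the advantage
is a small-model phenomenon, not extra information.

**Equation recovery.** With response noise at 3–5% of the signal sd and
10 random distractor metabolites, stepwise selection recovers the exact
generating supports and coefficients within 10% in ≳95% of seeds at
n = 25. Failures are the textbook stepwise failure modes (a spurious
entrant at p ≈ 0.03, or a coefficient pulled by the pair correlation) —
worth keeping in mind when reading any single stepwise fit.

**Generator fidelity limits.** Linear band mixing, Gaussian noise and
linear trait equations omit real-data features: nonlinear
absorbance/scattering, correlated instrument drift, microbial community
dynamics, batch structure across animals, and metabolite cross-talk.
Passing these experiments validates the pipeline's mechanics and its
behaviour under the stated statistical structure; it does not validate
the biology, nor predict the R² obtainable on real meat.

## Numerical conventions and edge cases

Seeds derive per stage as `default_rng([seed, tag])`. NIPALS truncates
(with a warning) when the X residual is exhausted. Zero-variance columns
under autoscaling, constant rows under SNV, zero rows under
normalization, empty ROI masks, white ≤ dark calibration frames, and
singular OLS designs all raise typed errors naming the offender.
Constant truth vectors make R² undefined → NaN with a warning. Ties in
LV selection resolve to fewer components; ties in the preprocessing grid
resolve to grid order; indicator-selection ties resolve by R²CV, then
alphabetically.

## Problem sizes used by tests and the acceptance script

Unit and integration tests run the cascade at reduced augmentation
(150–1,000 rows) and small LV budgets, chosen as the smallest sizes at
which every qualitative property of the full-size pipeline is already
stable. The acceptance script runs the full default sizes (n = 10,000,
7,000/3,000, 2,100:900) for the single cascade, 50 seeds for equation
recovery and 30 paired seeds at n = 2,000 for the combination
experiment.

## Not implemented (by design)

ENVI hypercube I/O (tabular text is the canonical interchange; raw
scans are in-memory objects), Savitzky–Golay/derivative/OSC
preprocessing, SIMPLS or sparse PLS variants, regularized or robust
regression, coefficient uncertainty intervals, ANOVA/post-hoc trait
comparisons, and any figure generation.
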