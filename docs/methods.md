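# Methods

## Framework calculators

All formulas are implemented exactly as used at the bedside, in mmol/L
(albumin g/L, PaCO₂ mmHg), with no internal rounding; comparisons against
printed tables round half-away-from-zero to the table's precision.

* Traditional: AG = (Na + K) − (Cl + HCO₃); AGc = AG + 0.25 × (42 − albumin).
* Stewart: SIDa = (Na + K + Ca + Mg) − (Cl + lactate), with calcium and
  magnesium entering at their reported mmol/L values (no valence doubling —
  this matches the convention of the source formulas, not ion-equivalence
  arithmetic). [Alb⁻] = (0.123·pH − 0.631)·albumin;
  [Pi⁻] = Pi·(0.309·pH − 0.469); ATOT = [Alb⁻] + [Pi⁻];
  SIDe = bicarbonate term + ATOT; SIG = SIDa − SIDe.
* Partitioned base excess: BECl = Na − Cl − 35; BEAlb = 0.25 × (42 −
  albumin); BELac = 1 − lactate; BEGap = SBE − BECl − BEAlb − BELac. The
  decomposition sums to SBE identically by construction.

**Effective-SID bicarbonate term.** Two modes are provided. `formula`
evaluates the Henderson–Hasselbalch CO₂ term 0.0301·PaCO₂·10^(pH−6.1);
`measured_hco3` substitutes the analyzer-reported bicarbonate. The worked
clinical cases shipped with the package reproduce their published SIG only
in `measured_hco3` mode, while `formula` mode is exactly invertible and is
therefore the default for cohort-level analysis and the synthetic-data
engine. The two SIGs differ by exactly (measured HCO₃ − CO₂ term), which is
a tested identity.

**Worked-case fixture.** Three published illustrative ICU cases are
packaged as CSV. 18 of their 24 printed derived values follow
arithmetically from their printed inputs and are asserted; the remainder
are mutually inconsistent (case 2's ATOT/SIG imply an albumin near 38 g/L
against the printed 24; case 2's BEGap and case 3's BECl/BEGap do not
follow from the printed Na/Cl/SBE; case 1's SIG computes to 1.5 vs the
printed 1.6). Inconsistent cells are excluded and flagged, never silently
"corrected".

**Standard base excess.** Clinical SBE comes from the analyzer; synthetic
records need a formula. We use a Van Slyke form
SBE = 0.9287 × (HCO₃ − 24.4 + 14.83 × (pH − 7.4)), zero at the reference
point (7.40, 24.4). The constants are module-level and swappable; no
temperature or hemoglobin corrections are applied.

**Units.** Albumin is g/L everywhere; the CSV reader rejects albumin below
10 as a plausible g/dL input. Magnesium and phosphate conversions use
0.41152 and 0.323 (mg/dL → mmol/L) with optional raw-field consistency
checks.

## Forward solver

The synthetic engine inverts the effective-SID equation: given
`sid_effective = SIDa − xa` (the strong-ion charge left after the latent
unmeasured anion load), albumin, phosphate and PaCO₂, it finds the pH at
which sid_effective equals the buffer charge
0.0301·PaCO₂·10^(pH−6.1) + [Alb⁻](pH) + [Pi⁻](pH). The right side is
strictly increasing in pH, so the root is unique when it exists. Brent's
method on the fixed bracket pH ∈ [6.5, 7.9] (tolerance 1e−10) is used;
states with no sign change on the bracket are rejected as unphysiological
rather than extrapolated. Water dissociation and minor species are
deliberately omitted: the solver inverts exactly the SIDe equation the
backward calculators use, which is what makes the round-trip identity
(formula-mode SIG of a reconstructed record equals the injected `xa` to
1e−6) hold and testable. This forward model is the package's construction
for data synthesis, not a published model.

## Synthetic cohort generator

**What it emulates.** An ICU admission cohort: one arterial sample per
patient, marginal medians/IQRs matched to published admission targets
(Na 138 (135–141), K 4.09 (3.63–4.59), Ca 1.17, Mg 0.80, albumin 31.2
(26–36.4), lactate 1.80 (1.20–2.95), Pi 1.23 (1.00–1.58), PaCO₂ 40.9
(35.0–47.7), Cl 104 implied). Families: normal for symmetric analytes,
lognormal (median/quartile-ratio matched) for the right-skewed positive
ones, skew-normal for the latent load. Chloride is generated as
Na − d with d ~ N(34, 3), a mild, stated Na–Cl coupling assumption (joint
correlations are not published); the implied chloride spread then matches
its 100–107 target.

**Latent unmeasured anions.** `xa` ~ skew-normal with median 3.5 mmol/L,
IQR matched to the published SIG distribution (1.42–6.35) and mild right
skew (shape 2), admitting negative values (net unmeasured cations). The
skew-normal's location/scale/skew parametrization fits the spec of the
latent load directly and keeps the sign unconstrained.

**Measurement noise** is added after equilibrium solving, so pH, HCO₃ and
SBE carry analyzer-like mutual inconsistency. Defaults are 1-SD
imprecisions of a blood-gas analyzer and a central laboratory: pH 0.003,
PaCO₂ 0.8 mmHg, HCO₃ 0.2, SBE 0.25, Na 0.7, Cl 0.8, K 0.04, Ca 0.01,
Mg 0.02, lactate 0.06, albumin 0.8 g/L, Pi 0.04 (mmol/L unless noted).
With zero noise, recomputed SIG equals `xa` exactly; at default noise the
generated cohort (n = 2000, seed 42) yields corr(BEGap, −xa) ≈ 0.91 and
corr(SIG, xa) ≈ 0.95.

**What it does not emulate**: longitudinal trajectories, diagnosis-specific
subpopulations, analyzer drift, preanalytical error, missingness, or the
outcome structure (mortality, severity scores) of a real ICU. Passing tests
therefore demonstrate internal validity of the methods against known ground
truth, not clinical performance on real patients.

**Resampling.** Draws that violate positivity or have no charge-balance
root in pH [6.5, 7.9] are discarded and redrawn from the same stream
(counted, hard-capped), preserving seed determinism.

**Temporal split.** Generation order stands in for admission date; the
first ⌈frac·n⌉ records form the development cohort (frac = 0.654 reproduces
a 2274/1202 partition of 3476 records). An optional per-column location
drift can be applied to the validation half to emulate secular shifts; the
default is no drift.

## Agreement analysis

Classification bands: AGc normal in [7, 17] mmol/L; SIG and BEGap
referenced to 0. A strict zero reference would classify essentially every
patient as abnormal, so a configurable half-width (default 2 mmol/L) around
the centers is treated as normal — the published analysis implies such a
band without printing one, so the published reclassification counts are not
comparison targets. Sign conventions: high AGc/SIG and low BEGap mean
unmeasured anions. Pearson correlation (matching the source analysis),
Cohen's kappa computed from the 3×3 contingency table with the marginal
chance correction (the degenerate single-category table returns 0), and
reclassification counts conditioned on AGc-normal patients. The
correlation/agreement dissociation — |r| > 0.8 with κ < 0.5 under center
shifts — is reproduced as a generated test case.

## Model benchmark

Feature sets per framework: traditional (PaCO₂, HCO₃, AGc), Stewart
(PaCO₂, SIDa, ATOT, SIG), partitioned BE (PaCO₂, BECl, BEAlb, BELac,
BEGap); target is arterial pH. Panels for modelling use formula-mode SIG.

* **MLR**: OLS with intercept; adjusted R², Durbin–Watson, 95% coefficient
  CIs. Predictor importance is the Shapley/LMG decomposition of R² (average
  marginal R² contribution over all predictor orderings), normalized to sum
  to one. This is a reconstruction: the source column it mirrors is not
  defined anywhere, and LMG is the standard relative-importance measure
  with the observed behaviour (non-negative shares summing to one).
* **ML**: random forest (500 trees, min_samples_leaf 5), XGBoost (300
  rounds, learning rate 0.1, depth 6), SVR (RBF, C 10, ε 0.01, features
  standardized inside the estimator pipeline). Hyperparameters are fixed,
  never searched. The leaf-size floor for the forest is a deliberate
  regression-smoothing choice; unbounded trees on cohorts of this size add
  compute and variance without improving the comparisons made here.
* **Protocol**: seeded 80/20 train/test split; 10-fold CV (folds seeded,
  all preprocessing fit within each training fold); calibration on held-out
  predictions: calibration-in-the-large = mean(obs − pred), slope/intercept
  from regressing observed on predicted (undefined for constant
  predictions, reported missing; exact identity short-circuits to
  (0, 1, 0, 0)), Brier-style MSE.
* **Importance**: impurity-based tree importance; exact Shapley values —
  XGBoost via its built-in exact tree-SHAP predictor, random forests via
  this package's own exact enumeration (path-dependent conditional
  expectations over all 2^M feature subsets, numba-compiled; exact because
  M ≤ 5, verified against a brute-force oracle and the efficiency
  property). Shapley evaluation uses up to 200 held-out rows (an average of
  exact per-row values; the cap bounds compute, not bias). SVR uses
  permutation importance (20 repeats, mean R² drop). The composite ranking
  averages tree and Shapley scores; by default each vector is normalized to
  sum to one first (shares sum to 1), with a raw-mean option matching the
  convention under which published combined columns reproduce from their
  printed inputs.
* **Ablation**: the framework's unmeasured-ion index (AGc, SIG, BEGap) is
  removed and full vs reduced models are compared under identical 10-fold
  assignments (pairing asserted by a fold hash); ΔR² = full − ablated CV
  mean. On default synthetic cohorts the ordering is stable: removing SIG
  or BEGap costs ΔR² ≫ 0.15, removing AGc costs ≈ 0.

Problem sizes in tests and the pipeline default to n = 2000 cohorts with a
0.654 development fraction; multi-seed properties use five seeds with
XGBoost, the most stable algorithm across frameworks here.

## Pipeline

`run_pipeline` chains cohort → split → panels → agreement → benchmark →
external replay on the validation half → worked cases, writing every stage
output plus a manifest with SHA-256 checksums. Stage outputs are
byte-identical across runs of the same config/seed (the manifest timestamp
is the only varying field); development-half fitting never sees
validation-half panels.

## Known limitations

* The forward model is the minimal single-equation Stewart balance: no
  multi-pK albumin model, no water dissociation, no CO₂ transport dynamics,
  no temperature dependence.
* Marginals are moment-matched to published summaries; true joint structure
  (beyond the stated Na–Cl coupling) is unknown and not modelled.
* Real-cohort performance numbers (adjusted R², κ, r from the source
  clinical study) are cohort-specific and are not reproduction targets;
  the package reproduces the qualitative pattern — ordering of frameworks,
  importance ranks, ablation asymmetry, correlation/agreement dissociation
  — on synthetic data with known ground truth.
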