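# Methods

This note documents the models and numerical choices behind `coldstun-mpi`:
what the scores compute, what the diagnostic machinery assumes, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## The scoring model

A mortality-prediction index is a sum of banded point penalties. For each
analyte the table defines intervals ("bands") on the high-abnormal and/or
low-abnormal side of a normal gap; a value inside a band earns that band's
points, a value in the normal gap (or in a gap between printed bands) earns
zero, and the index score is the sum over the index's analytes. Scores are
therefore non-negative integers bounded by the sum of each analyte's maximum
band points (e.g. 32 for MPI1, 24 for MPI6).

Interval conventions, applied uniformly:

* printed ranges "a–b" are closed `[a, b]`; "≥a" is `[a, ∞)`; "<b" is open
  at `b`. Values are compared at full floating precision — no rounding
  before banding.
* **Tie rule.** Where two printed bands share an endpoint (the MPI1
  potassium bands `1.5–2.0` at 6 points and `2.0–2.4` at 4 points both
  contain 2.0), the value takes the **higher** points. This is the
  conservative direction for triage and documents, rather than hides, the
  overlap in the source tables.
* **Partial rows.** Some table rows print fewer cells than the table has
  point columns. Cells are anchored at the extreme — the open-ended `≤/≥`
  cell takes the row's maximum points — and walk inward one column per
  cell, so severity always increases toward the extreme.
* **Known coverage gap.** The MPI3 chloride low side leaves `[99, 100)`
  uncovered (the printed cells are `105–110`, `104–100`, `<99`). The gap
  scores 0; no band is invented. Chloride is excluded from all refined
  indices, so this cannot affect MPI4/5/6 classification.

The band tables ship as a versioned JSON resource
(`coldstun_mpi/data/band_tables.json`) and can be overridden by path. The
loader refuses tables whose points fall outside the table's printed column
set, whose severity is not strictly increasing toward the extreme, or whose
bands overlap beyond a shared endpoint.

Classification is `deranged` iff score ≥ cut-off (inclusive). MPI4/5/6
carry their published cut-offs (10, 6, 8); MPI1–3 require an explicit one.

## Blood-gas preprocessing

Raw analyser values are corrected from electrode temperature to cloacal
body temperature with coefficient-set-driven forms: additive for pH
(slope · ΔT), log-linear for pCO₂ and pO₂ (`· 10^(k·ΔT)`). Bicarbonate is
derived via Henderson–Hasselbalch, `HCO₃⁻ = α(T) · pCO₂ · 10^(pH − pK(T))`,
the anion gap as `(Na [+K]) − (Cl + HCO₃)` (potassium included by default,
matching common point-of-care analysers), and ionized calcium is
standardised to a target pH multiplicatively, `iCa · 10^(s·(pH−pH_target))`.

All coefficients are **data**: a named set in a YAML/JSON config with a
provenance label. The bundled `human-default` set uses the standard human
constants (pH slope −0.0147/°C, pCO₂ factor 10^(0.019·ΔT), pO₂ factor
10^(0.0052·ΔT), α = 0.0307 mmol·l⁻¹·mmHg⁻¹, pK′ = 6.1, iCa slope 0.24).
Species-specific corrections for sea turtles differ — especially for pO₂ —
so a `kemps-ridley` placeholder exists whose coefficients the user must
transcribe from the species literature; using it unfilled raises a
configuration error naming the missing function rather than silently
falling back to human constants. Loaded sets are validated over their
supported temperature range (α > 0, pK ∈ [5.5, 7.0]).

Measured values always take precedence over computed ones; derived analytes
are filled in only where absent and where their inputs are present.

## Diagnostic evaluation

Orientation is fixed: positive class = died within 7 days, test-positive =
score ≥ cut-off. From the integer confusion counts, SE = TP/(TP+FN),
SP = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), LR+ = SE/(1−SP),
LR− = (1−SE)/SP. PPV/NPV with a zero denominator are reported as undefined
(`nan`); LR+ is `+∞` at perfect specificity with non-zero sensitivity.
Fractions are carried exactly and rounded only at presentation: SE/SP to
two decimals, PPV/NPV to one decimal (shown with a trailing zero), LR to
two decimals, all half-up.

The empirical ROC curve places an operating point at every distinct
observed score plus the trivial endpoints; the trapezoidal area equals the
Mann–Whitney pair statistic with ties counted ½ (asserted to 1e−12 against
a brute-force pair-counting oracle, and cross-checked against
scikit-learn). A cohort with all-identical scores yields the degenerate
two-point diagonal and AUC 0.5 — documented, not an error.

AUC confidence intervals: **DeLong** (default; placement-component variance,
normal quantiles, clipped to [0, 1]), **Hanley–McNeil** (the classic
Q₁/Q₂ approximation), and a **stratified percentile bootstrap** (2000
resamples by default, reproducible under a fixed seed). On moderate cohorts
the three agree to ~0.02–0.03 per bound; coverage of the DeLong interval is
asserted near-nominal (a-priori band 0.90–0.99 over 200 seeded binormal
replicates at n = 500/500, true AUC 0.896).

"Both sensitivity and specificity optimised" is implemented as **Youden's
J** = SE + SP − 1, ties broken toward the lower cut-off (favouring
sensitivity). A closest-to-(0, 1) criterion is available behind a flag;
note that on the published MPI4 rows it selects 8 rather than the published
10, so Youden is the criterion of record. Index refinement keeps an analyte
iff its standalone banded-score AUC is ≥ 0.7 (boundary inclusive).

Prevalence-adjusted predictive values use Bayes' rule; PPV is monotone
increasing and NPV monotone decreasing in the assumed mortality proportion.
Identity checks (count-based PPV/NPV ≡ the Bayes formulas at the cohort's
own prevalence, to 1e−12) run over random confusion matrices.

The published per-cutoff performance rows of MPI4/5/6 (class sizes 25/118)
ship as a data resource; the suite reconstructs integer counts from each
row's SE/SP and reproduces all printed statistics at printed precision. One
cell (MPI6 table, cut-off 4, LR−) is internally inconsistent with its own
row under any uniform rounding rule; the resource records it as an erratum
with the arithmetically consistent value (0.08 rather than the printed
0.07), and the test asserts the consistent value.

## The synthetic cohort

No per-animal data accompany the published indices, so the generator
emulates a two-class admission cohort statistically. Defaults are a stated
world, fixed once:

* 143 animals, mortality 0.175, outcome counts fixed by rounding so the
  proportion is exact (Bernoulli sampling behind a flag);
* survivor marginals centred on an unremarkable admission panel (pH 7.55,
  pCO₂ 30 mmHg, pO₂ 80 mmHg, Na 150, K 3.5, Cl 115, iCa 0.9, glucose 5
  mmol/l, osmolality 330 mOsm/kg), normal for pH, lognormal for
  concentrations and partial pressures (positive, right-skewed), truncated
  to sanity bounds by rejection;
* non-survivors shifted in the four consistently reported derangement
  directions — pH −0.4, pCO₂ +15, pO₂ −30, potassium +2.5 — with wider
  spreads and milder drifts elsewhere;
* body temperature N(9, 3) °C truncated to [2, 20] °C (cold-stunned
  juveniles at admission);
* acid–base coherence: a Gaussian-copula correlation of −0.5 between the
  pH and pCO₂ z-scores, bicarbonate derived per-animal via
  Henderson–Hasselbalch (`human-default` set) and anion gap from the
  four-ion difference;
* one seeded `numpy` generator per cohort; identical spec + seed gives
  byte-identical CSV output.

What a green test does and does not establish: the generator reproduces the
*direction* and internal coherence of the published derangements and
exercises every pipeline stage, but the SDs and shifts are illustrative,
not estimates of the study population (no cohort means/SDs were published).
Under the defaults MPI6 separates the classes more cleanly (AUC ≈ 0.98 at
n = 2000) than the real cohort did (published AUC 0.896); the null
configuration (identical class distributions) sits at AUC ≈ 0.5. Generator
calibration is checked against the closed-form binormal AUC
Φ((μ₊−μ₋)/√(σ₊²+σ₋²)), with empirical AUC within 0.02 at n = 5000/class.

## Known limitations

* The species-specific blood-gas coefficients are not bundled (they live in
  the cited species literature); out of the box, preprocessing uses human
  constants and says so via the provenance label. Scores computed from
  analyser-auto-corrected pO₂ are **not** interchangeable with scores from
  the correction formulas used here.
* The published study AUCs (0.806/0.864/0.896) and their CIs cannot be
  reproduced without the unreleased per-animal cohort; the suite
  substitutes property-based checks (pair-statistic equivalence, identity
  algebra, binormal calibration, CI coverage).
* The indices are decision support for triage and treatment prioritisation;
  they are explicitly not a euthanasia criterion, and a falsely positive
  score is expected in roughly half of test-positives at ~17.5 % mortality.
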