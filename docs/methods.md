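# Methods

## Temperature model and screening statistics

One exam comprises 44 measurements: 10 points per breast × 2 channels
(internal `mw`, skin `ir`) plus reference points T1/T2 in both channels.
Temperatures are °C, stored unrounded; rounding to 0.1 °C happens only at
display. Missing values are rejected at scoring time — partial exams are
not imputed. The plausibility window [20, 45] °C is configurable.

**Q_max** pools the 20 breast temperatures per channel (reference points
excluded — they are measurement controls, not gland tissue) and takes the
larger of the two `max − mean` excesses. A hot focus raises the maximum
far more than the pooled mean, so Q_max measures focal heating relative to
the gland average; it is invariant to adding a constant to all breast
temperatures.

**Asymmetry coefficients.** `k_int` and `k_skin` are the maximum
left–right differences at symmetric points. We use the *absolute*
difference by default so a right-sided tumour scores identically to a
left-sided one; the signed left-minus-right convention (under which
heating any left-breast point is monotone in `k`) is available via
`signed=True` and the `RunConfig.signed_asymmetry` flag. Argmax ties break
to the lowest point index for determinism.

**R.** If both channels peak at the same point, `R = k_int + k_skin`.
Otherwise the larger `k` (channel tie broken toward the internal channel)
is augmented by the other channel's difference at its peak point — the
cross-channel branch. The absolute convention keeps both branches
non-negative and side-symmetric.

**Decision rule.** Strictly above both thresholds (2.0 / 2.5 °C) →
malignancy suspected; strictly below both → benign; otherwise ambiguous.
Boundary equality is classified ambiguous because the rule is defined only
for strict inequalities; clinically this errs toward further work-up.

## Feature space

The classifier input is a fixed, versioned 74-vector: the four derived
10-vectors (per-breast internal gradients `T_mw − T_ir`, per-channel
signed asymmetries `left − right`), min/max/mean/range aggregates of those
four and of the four raw breast groups, plus Q_max and R. The exact
aggregate list is a design choice (the useful families — spread,
hot-area maximum, gradients, asymmetries — are known; the precise set is
not canonical) and is declared in `FEATURE_NAMES` / `RunConfig.aggregates`.
Asymmetry stays signed here, unlike in R's computation, because a learner
can exploit sidedness. Reference points are excluded by default.

## Risk classifier

A deliberately compact, fully reproducible classifier: logistic regression
(default) or a one-hidden-layer MLP (16 units), both behind a
StandardScaler, with balanced class weights for the ~8:1 low:high cohort
imbalance. Training uses a stratified 80/20 split keyed on the seed; the
reported F1/precision/recall describe exactly the returned model (fitted
on the 80% portion). Models serialise to JSON (architecture + weights) and
reload into a dependency-light predictor that reproduces predictions to
machine precision.

## miRNA oncopanel

Eight markers with fixed risk directions: miR-155, miR-199a-3p,
miR-222-3p and miR-21-5p are oncogenic (elevation = risk); let-7a-5p,
miR-196a-2, miR-106a-5p and miR-137 are protective (reduction = risk).
The fold change (pathology/norm concentration, copies/μL, reported
half-up to 1 decimal) is converted to an *effective magnitude ≥ 1* in the
marker's risk direction — protective markers use the reciprocal; a change
against the risk direction is neutral (magnitude 1). Magnitudes bin into
half-open bands [1.5, 2) → 1, [2, 5) → 2, [5, ∞) → 3; the published band
edges overlap at 2 and 5, and we assign boundaries to the upper band
(configurable). The panel risk factor is the sum (0–24); the low/high
cutoff defaults to 5, interpolated between the published anchors (3 → low,
7 → high) and configurable.

Marker names are canonicalised (case, `Hsa-/Has-/Micro-RNA-` prefixes);
`miR-196a-3p` is accepted as a printed alias of the 199a-3p panel slot,
which appears under both names in published tables.

Known inconsistency in the published example: the concentration table
marks miR-155 (fold 7.1) and miR-21-5p (fold 5.0) as the same visit whose
label table calls them "Norm", while markers at fold 0.2/0.6 are labelled
"Slight increase". No threshold reading maps those concentrations onto
those labels, so both scoring paths are implemented independently; their
agreement is asserted only on synthetic, internally consistent panels.
The concentration units are treated as linear copies/μL (the printed fold
changes are linear ratios of the printed concentrations).

## Combined assessment

The fusion rule codifies the two-visit clinical workflow as an explicit,
total decision table over (MWR class, classifier label, panel category):
MWR suspicion refers unless contradicted by a low panel (→ discordant,
human review); a benign MWR with a high classifier flag recommends the
panel, and a low panel then returns the patient to monitoring; a high
panel always escalates and never downgrades. Every rule fired is recorded
in an ordered rationale trace. The table is a design choice distilled from
a narrative, not a validated clinical protocol, and the ">85% probability"
sentence attached to above-threshold MWR results is echoed as text only —
no calibration data exists to compute it.

## Synthetic data generator

The generator realises the conceptual thermogram signatures, not tissue
physics (no bioheat PDE, no antenna model):

- healthy: skin ≈ 31.5 °C, internal ≈ 34.5 °C, i.i.d. Gaussian noise
  sd 0.25 °C per point and channel; no focus; skin spread stays well below
  the 2 °C at-risk signature.
- high risk: an internal hot focus of `focus_delta_int` (default 3.0 °C)
  at one point, half amplitude at adjacent points, on one side; the
  matching skin points rise by `focus_delta_int − focus_gradient_reduction`
  (default reduction 1.0 °C), producing the reduced internal gradient, the
  >2 °C skin spread and the bilateral asymmetry at once. The gradient
  reduction also stands in, crudely, for capsule-masked lesions.

Baseline means, noise level and focus amplitude are invented defaults —
no raw population temperatures are published — chosen to sit in the
physiological range and exposed in `RunConfig`. Calibration properties are
regression-tested: the healthy profile classifies benign in ≥95% of 200
seeded draws and the high-risk profile escapes benign in ≥90%; the
500+60 synthetic cohort (the study's ~8:1 imbalance at desk scale) is
constructed to be learnable, and the stand-in classifier reaches held-out
F1 ≥ 0.9 on it. That figure is a property of the generator's separability,
an analog of — not a reproduction of — any clinically reported accuracy;
passing it says the pipeline wiring is sound, nothing about real patients.

Panel profiles draw norm concentrations lognormally (sd 0.1 in log space)
around published healthy-reference means and apply per-marker fold
multipliers in each marker's risk direction; the default high-risk
multipliers are the published clinical panel's exact ratios, so the
noise-free generator reproduces its printed fold changes.

## Numerical choices

Scoring uses exact float arithmetic; no intermediate rounding. Fold-change
reporting rounds half-up via `decimal`. Argmax/channel ties break low
index / internal channel. Problem sizes in the test suite (200 draws per
calibration check, 1000 exams for the oracle comparison, 5 × 560-patient
cohorts) keep the full suite under a few seconds while leaving the
binomial acceptance margins wide.

## Limitations

Real thermograms have spatially correlated, patient-specific baselines,
menstrual-cycle and ambient drift, and device noise none of which the
i.i.d. generator models; the classifier's perfect synthetic F1 will not
transfer. The decision table and the panel cutoff are interpolations from
a single worked example. The qPCR preprocessing chain (Ct values, standard
curves) is out of scope — the panel scorer starts from concentrations.
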