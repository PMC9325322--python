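# Methods

## Scope and data model

The package analyses elderly (≥ 65 y) patients exposed to oral
anticoagulants — warfarin (B01AA03) and the DOACs apixaban (B01AF02),
rivaroxaban (B01AF01) and dabigatran (B01AE07) — around one index
hospitalization, using five pre-linked tables: patients, community-pharmacy
dispensings, in-hospital administrations, hospital stays with positioned
ICD-10 codes, and INR / hemoglobin results. Record linkage itself is out of
scope; inputs arrive keyed on `patient_id`. Patients with no anticoagulant
exposure in either setting are excluded at pipeline level with a reported
count; infra-day stays and under-65 patients are rejected at load.

All dates are ISO-8601 calendar dates and every exposure interval is closed
on both ends. The two detection windows are the closed 30-day pre-admission
window `[admission − 30 d, admission − 1 d]` (primary care) and the stay
`[admission, discharge]` (hospital). The look-back horizon for
comorbidities, prior hospitalizations and exposure duration is 365 days.

**Drug eras.** A dispensing on day *d* with supply *s* covers `[d, d+s−1]`;
an administration covers its day. Per (patient, drug, setting), covered
intervals are unioned, merging across uncovered gaps of at most
`gap_tolerance_days` (default 0). The dispensing coverage duration is not an
attribute of claims data; the default `supply_days = 30` follows the monthly
dispensing convention of French community pharmacy and is configurable per
record. Era construction is idempotent and its day coverage equals the union
of per-record coverage days (property-tested against a brute-force day-set
oracle).

## Knowledge base

Interaction rules, PIM rules, code sets and the Charlson mapping live in one
versioned JSON bundle (`src/pimddi/data/kb.json`). Rules address ATC
*patterns*: a full 7-character code, or a prefix wildcard with optional
exclusions (`J01FA*!J01FA10` = macrolides except azithromycin). Pair
matching is unordered and case-insensitive.

Severity is dual-source: Theriaque levels (1 contraindicated, 2 not
recommended, 3 use with caution, 4 to take into account) and Micromedex
classes (contraindicated, major, moderate). Harmonization maps Theriaque
1–2 and Micromedex contraindicated/major to **major**, Theriaque 3 and
Micromedex moderate to **moderate**, Theriaque 4 to **minor**; when both
sources are present the more severe harmonized class wins — a
pharmacovigilance-conservative resolution chosen because no published
conflict rule exists. The mapping is total over the 19 valid input
combinations and monotone (upgrading either source never lowers the output).

The shipped mini-KB is restricted to published anticoagulant pairs:
the warfarin Beers combinations; apixaban/rivaroxaban with the dual
CYP3A4 + P-gp inhibitors amiodarone, verapamil, diltiazem, ciclosporin and
dronedarone; dabigatran (a P-gp substrate) with P-gp inhibitors;
warfarin/rivaroxaban with the CYP2C9/2C19-inhibiting SSRIs escitalopram,
paroxetine and citalopram; and pharmacodynamic bleeding pairs (salicylates,
NSAIDs, tramadol, heparins, paracetamol, atorvastatin, levothyroxine).
Severity levels are taken from published values where available
(`source: "printed"`), otherwise they default to Theriaque level 3 with
`source: "curated-default"`. Anticoagulant–heparin pairs model the
temporary co-prescription during a treatment switch and can be excluded at
load (`include_heparin_pairs=False`).

The bleeding ICD-10 set covers anticoagulant-induced hemorrhagic disorder
and adverse-effect codes (D68.3, Y44.2, T45.5), hematuria (R31, N02), acute
post-hemorrhagic anemia (D62), recto-anal hemorrhage (K62.5),
gastrointestinal bleeding (K92.0–K92.2), epistaxis (R04.0), unspecified
hemorrhage (R58) and intracranial hemorrhages (I60–I62); matching is
prefix-based on 3–4-character roots with dots ignored, and the set is
user-replaceable. The antidote set is exactly {B02BA02, V03AB37, V03AB38,
B02BD01}. Renal impairment defaults to any look-back N18*/N19 code, with a
per-patient boolean override for eGFR-based flags.

## Detection semantics

Co-exposure requires ≥ 1 day of era overlap inside the setting window
(the window is published; the overlap rule is the package's choice). One DDI
event is emitted per unordered interacting pair per patient and setting;
when several rules match a pair the most severe wins. PIM classification
returns the most specific triggered condition: an unconditional age
threshold before the age-plus-renal condition, and for warfarin a Beers
partner era overlapping a warfarin era inside the window. A DDI is a
PIM–DDI iff its anticoagulant member holds a PIM finding in the same
setting, or the pair itself is a warfarin Beers combination. Triple
combinations (e.g. warfarin–amiodarone–paracetamol) are represented as
pairwise events sharing a combo context — the sorted tuple of
same-anticoagulant drugs whose co-exposure intervals intersect — from which
triple rows of the rate tables are assembled.

Mechanism tables are patient-level: each patient with events is classed
pharmacokinetic if any event is pharmacokinetic, else pharmacodynamic, and
PD/PK percentages are taken over classed patients; PK subtype rows count
patients with ≥ 1 event of the subtype as a share of PK patients (a patient
can contribute to several subtypes, so subtype shares need not sum to 100).

## Bleeding-ADE phenotype

The composite fires on any of: (1) a bleeding ICD-10 diagnosis on the index
stay; (2) any in-stay INR **strictly** greater than 5; (3) any in-stay
hemoglobin at or below the sex-specific minimum usual value — ≤ 11 g/dL for
men, ≤ 10 g/dL for women, both **inclusive**; (4) any in-stay antidote
administration. All fired criteria are recorded with their evidence, and
the composite provably equals the OR of the four detectors. The default
hemoglobin mode is threshold-only because the operative cut-offs are the
defined minimum usual values; an optional delta mode additionally requires
a ≥ 2 g/dL drop from the patient's pre-stay maximum. The phenotype is
attributed to the index stay only; look-back bleeding stays feed the
"previous bleeding event" covariate instead. The denominator is patients
with primary-care anticoagulant exposure in the 30 days before admission.

## Pathway classification

Each patient receives exactly one label: *continued* (exposed in both
settings; molecule switches count as continued anticoagulation),
*discontinued_bleeding* / *discontinued_surgery* / *discontinued_other*
(pre-hospital exposure only, with reason precedence bleeding > surgery >
other — a chosen precedence, since a patient can both bleed and undergo
surgery), *initiated_in_hospital*, or *none*. Subcategory counts sum to the
discontinued total and labels partition the cohort; the residual
*discontinued_other* bucket deliberately pools causes that are not
observable in claims (short stays, unreconciled medication, switches to
parenteral heparins).

## Statistical modelling

**Charlson score** — Quan ICD-10 category mapping with the original
weights (a chosen mapping; none is mandated). Each category counts once;
hierarchical pairs (complicated vs. uncomplicated diabetes, moderate/severe
vs. mild liver disease, metastatic tumor vs. any malignancy) count only the
more severe member.

**Logistic regression** — bleeding ADE on 12 covariates: male sex, age in
years (untransformed; the age OR is per-year), history of stroke, previous
bleeding event, diabetes, renal disease, liver disease, cancer,
hypertension, and the PIM / DDI / PIM–DDI indicators. Maximum likelihood
via `statsmodels.Logit`; ORs are exponentiated coefficients with Wald 95%
CIs; p-values are raw (no multiple-testing correction). Rank deficiency
raises an error listing collinear columns; (quasi-)perfect separation —
a zero cell in a binary covariate's outcome table, or runaway
coefficients — raises an error naming the covariate.

**ML workflow** — 80/20 split stratified on the outcome; SMOTE to equal
class counts with `k = 5` (the algorithm's canonical default), synthetic
rows being convex combinations of a minority row and one of its *k* nearest
minority neighbors, with all-binary columns copied from the seed row rather
than interpolated; 10-fold stratified, seeded cross-validation selecting
hyperparameters by mean ROC AUC over compact grids (trees ∈ {200, 500},
depth ∈ {3, 6, unlimited for RF}, learning rate ∈ {0.05, 0.1} for boosting,
RBF-SVM cost ∈ {0.1, 1, 10}); SMOTE is applied inside each fold by default
so no validation-fold information reaches the oversampler, with a
compatibility flag to rebalance once up front. The operating threshold is
the observed score cut-point minimizing the Euclidean distance of
(sensitivity, specificity) to (1, 1), ties broken toward higher
sensitivity; it carries a provenance tag and evaluation refuses thresholds
not selected on training data. ROC AUC is trapezoidal over unique score
cut-points. Variable importance is gain-based (XGBoost gain; RF impurity
decrease), normalized to sum 1. Percentages throughout the reporting layer
are rounded half-up to one decimal.

## Synthetic cohort generator

The generator emulates the linked structure top-down so the detection
pipeline recovers planted labels exactly. Per patient it draws: pre-hospital
exposure (69.3%), age (29.5% uniform on 65–74; above 75 an exponential tail
with scale 13 y, giving ~70.5% ≥ 75 and median ≈ 79), sex (57.8% male),
comorbidities (stroke 5%, previous bleeding 8%, diabetes 25%, renal 15%,
liver 3%, cancer 5%, hypertension 60% — chosen as realistic for an elderly
anticoagulated cohort), and the joint PIM/DDI flags with marginals 22.9% /
47.2% and PIM∧DDI = PIM–DDI = 19.5%. The anticoagulant molecule is then
drawn from the configured shares *restricted to flag-consistent candidates*
(a warfarin PIM requires a Beers partner, which is also a DDI, so
PIM-without-DDI patients carry a DOAC; renal impairment is forced on when no
drug could otherwise satisfy the PIM flag). Interacting co-medications are
drawn from per-anticoagulant partner pools that map one-to-one onto KB
rules; background medications come from a pool outside every KB pattern.
Dispensings are written monthly with the last one inside the pre-admission
window; exposure-duration classes follow the configured shares
(6.5 / 9.3 / 8.2 / 76.0% for ≤ 1, 1–3, 3–6, > 6 months).

The bleeding outcome is drawn from a logistic model on the *realized*
covariates with planted log-ORs (sex 1.19, age 1.03/y, stroke 1.17,
previous bleeding 4.23, diabetes 1.29, renal 1.98, liver 1.72, cancer 2.68,
hypertension 1.72, PIM 1.08, DDI 1.15, PIM–DDI 1.23); the intercept is
calibrated by bisection so the expected marginal rate over the sampled
cohort hits the 17.1% target (within 0.5 pp; an unreachable target raises a
calibration error). Each ADE patient is assigned one detection criterion
(diagnosis 45%, INR 26%, hemoglobin 25%, antidote 4%) and the matching
evidence is written — a principal bleeding diagnosis, an in-stay INR in
(5.5, 8), a hemoglobin pushed below the sex threshold, or a vitamin-K
administration — while non-ADE patients' labs are truncated away from every
threshold (INR ≤ 4.5, hemoglobin ≥ threshold + 0.6) and their stays carry
only neutral and comorbidity codes. Pathways: 48.6% of pre-exposed patients
continue (anticoagulant and partners administered in-stay), the rest
discontinue with surgery assigned to 38.7% of non-bleeding discontinuations;
non-pre-exposed patients are in-hospital initiations.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: dosing and adherence variability, seasonal or
calendar structure, correlated comorbidity profiles (covariates are
independent apart from the flag-driven renal forcing), co-medications
outside the knowledge base's interaction patterns, hospital-setting
prevalence targets (hospital findings mirror the continued patients'
primary-care partners), the coexistence of PIM-only patients on warfarin,
and any deviation between the true outcome process and a logistic form.
The realized anticoagulant molecule mix also shifts toward warfarin
relative to the configured shares because flag consistency restricts the
candidate set. Closed-loop guarantees are therefore structural (flags,
labels, criteria recover exactly; rates recover within sampling error),
not a claim of clinical realism.

A statistical limitation follows from the Beers definitions themselves: the
PIM and PIM–DDI indicators coincide for all but ~3% of patients (the
configured marginals fix their disagreement mass), and both are nearly
determined by drug, age and renal status. The PIM/PIM–DDI contrast in the
logistic model is therefore weakly identified: refit estimates are
unbiased in their sum but individually noisy and anti-correlated, and the
Wald standard error understates the empirical sampling variability of the
PIM–DDI coefficient by roughly 10% at ~4000 patients, putting its CI
coverage near 92% rather than the nominal 95%. Replicated-recovery checks
of that coefficient sit correspondingly close to their acceptance margin,
while the well-identified covariates (age, previous bleeding, renal
disease, cancer, hypertension) recover comfortably.

## Problem sizes and numerical choices

Validation uses cohorts of ~400 patients for unit/property tests, ~5000
primary-care-exposed patients for prevalence recovery (binomial 95% CIs),
and 50 seeded replicates of ~4000-patient modelling cohorts for OR recovery
(each planted OR must fall inside the refit's 95% Wald CI in ≥ 90% of
replicates). ML tests and the reproduction script use compact
hyperparameter grids. Ties in threshold selection break toward higher
sensitivity, then the lower cut-point; constant scores return the single
degenerate cut-point with a warning; empty denominators yield explicit
empty tables rather than division errors. All randomness flows from a
single integer seed per run; regeneration with the same configuration and
seed is byte-identical.
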