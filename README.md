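# pimddi

Pharmacoepidemiology pipeline for **elderly patients on oral anticoagulants**
across the primary-care → hospital transition. Given linked longitudinal
tables (community-pharmacy dispensings, hospital stays with ICD-10 coding,
in-hospital drug administrations, INR / hemoglobin results), the package:

1. builds **drug eras** (continuous exposure intervals) per patient, drug and
   setting;
2. detects **potentially inappropriate medications (PIM)** among oral
   anticoagulants by Beers-type criteria — apixaban (≥ 65 y with renal
   impairment), dabigatran and rivaroxaban (≥ 75 y, or ≥ 65 y with renal
   impairment), and warfarin in named drug combinations (amiodarone,
   sulfamethoxazole/trimethoprim, ciprofloxacin, macrolides except
   azithromycin, NSAIDs);
3. detects bleeding-risk **drug–drug interactions (DDI)** from a curated,
   file-backed knowledge base of ATC-pattern rules with dual-source severity
   (Theriaque levels 1–4 and Micromedex classes, harmonized to
   major/moderate/minor) and mechanism classes (pharmacodynamic, CYP2C9/2C19,
   CYP3A4, P-gp, combined CYP3A4 + P-gp inhibition), in the 30-day
   pre-admission window and during the stay;
4. flags **PIM–DDI** — interactions whose anticoagulant member is itself a
   PIM;
5. phenotypes **hospitalization for bleeding adverse drug events** as the
   disjunction of four criteria: bleeding ICD-10 diagnosis, INR > 5,
   hemoglobin ≤ 11 g/dL (men) / ≤ 10 g/dL (women), or administration of an
   anticoagulant antidote (ATC B02BA02, V03AB37, V03AB38, B02BD01);
6. classifies the **anticoagulant treatment pathway** (continued /
   discontinued for bleeding, surgery or other reasons / initiated in
   hospital) and aggregates Sankey-style flow counts;
7. models bleeding risk with a **multivariable logistic regression**
   (odds ratios with Wald 95% CIs) and a **class-rebalanced ML workflow**:
   stratified 80/20 split, SMOTE oversampling, 10-fold cross-validated
   tuning of random forest / gradient-boosted trees / RBF-SVM, operating
   point at the threshold minimizing
   `sqrt((1 − sensitivity)² + (1 − specificity)²)`, gain-based variable
   importance.

Because real linked claims/warehouse data cannot be redistributed, the
package ships a **synthetic cohort generator** that emulates the linked
structure with configurable planted prevalences, a planted logistic outcome
model, and full per-patient ground truth, so every stage can be validated
end-to-end.

## Worked example

The frozen 12-patient cohort exercises every rule branch:

```python
from pimddi import load_kb, make_worked_example, run_pipeline, summarize_findings

tables, expected = make_worked_example()
result = run_pipeline(tables, load_kb())
print(summarize_findings(result))
```

```
                pim_trigger  n_ddi  n_pim_ddi    ade ade_criteria                pathway
patient_id
P01               age_ge_75      0          0  False               continued
P02         age_ge_65_renal      0          0  False               discontinued_other
P03                              0          0  False               discontinued_surgery
P04          warfarin_combo      2          2   True    diagnosis  discontinued_bleeding
P05               age_ge_75      1          1  False               continued
P06                              1          0  False               continued
P07                              1          0   True          inr  discontinued_bleeding
P08                              0          0   True   hemoglobin  discontinued_bleeding
P09               age_ge_75      0          0   True     antidote  discontinued_bleeding
P10         age_ge_65_renal      0          0  False               initiated_in_hospital
P11          warfarin_combo      1          1  False               discontinued_other
P12                              0          0  False               continued
```

Reading the rows: P04 (warfarin + amiodarone + paracetamol, 68 y) triggers
the warfarin Beers combination, so both of its pairwise interactions are
PIM–DDI and the melena diagnosis makes the stay a bleeding ADE; P05
(rivaroxaban, 80 y, + amiodarone) is an age-based PIM whose level-2 combined
CYP3A4 + P-gp interaction is therefore a PIM–DDI; P06 is the same pair at
70 y without renal impairment — a DDI but not a PIM–DDI; P12's azithromycin
is excluded from the macrolide rule and its INR of exactly 5 does not fire
(strict inequality).

A synthetic cohort with the default study conditions, via the CLI:

```bash
pimddi generate --n 2000 --seed 7 --out cohort/
pimddi prevalence --data cohort/
pimddi fit-logistic --data cohort/
pimddi predict --data cohort/ --family xgb --seed 7
```

## Layout

| module | role |
| --- | --- |
| `pimddi.data_model` | domain types, CSV dialects, drug-era construction |
| `pimddi.knowledge_base` | ATC pattern matching, severity harmonization, curated mini-KB (`data/kb.json`) |
| `pimddi.exposure` | anticoagulant exposure, PIM, DDI, PIM–DDI, mechanism tables |
| `pimddi.ade` | composite bleeding-ADE phenotyping |
| `pimddi.pathway` | treatment-pathway labels and flow counts |
| `pimddi.analytics` | prevalence / rate tables, Charlson index, logistic ORs |
| `pimddi.risk_model` | split, SMOTE, CV tuning, threshold selection, evaluation |
| `pimddi.synthetic` | cohort generator with ground truth; frozen worked example |
| `pimddi.pipeline` | end-to-end orchestration |
| `pimddi.cli` | thin command-line interface |

The shipped knowledge base is a deliberately small curated bundle of
published anticoagulant interaction pairs; the `kb.json` schema carries a
`source` field per rule so a licensed full interaction database can be
swapped in without code changes. See `docs/methods.md` for the model
assumptions, parameter choices and known limitations.
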