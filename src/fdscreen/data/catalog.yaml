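# Default clinical feature catalog: 13 Fabry-relevant features in 5 sign
# groups, each scored 0-3, with age modifiers for features that are typical
# of the elderly but significant when they manifest early, and feature-level
# exclusion (veto) conditions for confirmed alternative causes.
#
# RECONSTRUCTED DEFAULT: the exact feature wording and per-feature scores of
# the original scoring system are not public; this catalog is a documented
# reconstruction from the published description (see docs/methods.md).
# Membership and scores are configuration, not code.

features:
  - id: hypertrophic_cardiomyopathy
    name: Hypertrophic cardiomyopathy
    sign_group: cardiovascular
    base_score: 2
    evidence_terms: [hypertrophic_cardiomyopathy, lv_hypertrophy]
    icd10_prefixes: [I42]
  - id: myocardial_infarction
    name: Myocardial infarction
    sign_group: cardiovascular
    base_score: 1
    age_modifier: {below_age: 55, boosted_score: 2}
    evidence_terms: [myocardial_infarction]
    icd10_prefixes: [I21, I22, I25.2]
  - id: arrhythmia
    name: Arrhythmia / conduction abnormality
    sign_group: cardiovascular
    base_score: 1
    evidence_terms: [arrhythmia, conduction_abnormality]
    icd10_prefixes: [I44, I45, I46, I47, I48, I49]
  - id: renal_failure
    name: Renal failure / impairment
    sign_group: kidney
    base_score: 2
    age_modifier: {below_age: 55, boosted_score: 3}
    evidence_terms: [renal_failure]
    icd10_prefixes: [N18, N19]
    lab_findings: [reduced_egfr]
    exclusion_conditions:
      [nephropathy, amyloidosis, sarcoidosis, alport_syndrome,
       nephrectomy, urolithiasis, congenital_renal_defect]
  - id: proteinuria
    name: Proteinuria
    sign_group: kidney
    base_score: 2
    evidence_terms: [proteinuria]
    icd10_prefixes: [R80]
    lab_findings: [proteinuria_lab]
  - id: angiokeratoma
    name: Angiokeratoma
    sign_group: skin
    base_score: 3
    evidence_terms: [angiokeratoma]
  - id: hypohidrosis
    name: Hypohidrosis / heat-cold intolerance
    sign_group: skin
    base_score: 2
    evidence_terms: [hypohidrosis, heat_intolerance]
    icd10_prefixes: [L74.4]
  - id: stroke
    name: Stroke / TIA
    sign_group: neurological
    base_score: 2
    age_modifier: {below_age: 55, boosted_score: 3}
    evidence_terms: [stroke, tia]
    icd10_prefixes: [I63, I64, G45]
    exclusion_conditions: [patent_foramen_ovale, head_trauma]
  - id: neuropathic_pain
    name: Neuropathic pain / acroparesthesia
    sign_group: neurological
    base_score: 3
    evidence_terms: [neuropathic_pain, acroparesthesia]
  - id: hearing_loss
    name: Hearing impairment
    sign_group: neurological
    base_score: 1
    age_modifier: {below_age: 55, boosted_score: 2}
    evidence_terms: [hearing_loss]
    icd10_prefixes: [H90, H91]
  - id: gastrointestinal_symptoms
    name: Gastrointestinal symptoms
    sign_group: neurological
    base_score: 1
    evidence_terms: [abdominal_pain, diarrhea, nausea]
    icd10_prefixes: [K58, K59, R10]
  - id: recurrent_fever
    name: Recurrent fever
    sign_group: neurological
    base_score: 1
    evidence_terms: [recurrent_fever]
    icd10_prefixes: [R50]
  - id: cornea_verticillata
    name: Cornea verticillata / eye fundus lesions
    sign_group: eye
    base_score: 2
    age_modifier: {below_age: 55, boosted_score: 3}
    evidence_terms: [cornea_verticillata, eye_fundus_lesions]
    icd10_prefixes: [H18.0, H35]

conditions:
  - id: nephropathy
    name: Nephropathy
    terms: [nephropathy]
    icd10_prefixes: [N08]
  - id: amyloidosis
    name: Amyloidosis
    terms: [amyloidosis]
    icd10_prefixes: [E85]
  - id: sarcoidosis
    name: Sarcoidosis
    terms: [sarcoidosis]
    icd10_prefixes: [D86]
  - id: alport_syndrome
    name: Alport syndrome
    terms: [alport_syndrome]
    icd10_prefixes: [Q87.8]
  - id: nephrectomy
    name: Post-nephrectomy condition
    terms: [nephrectomy]
    icd10_prefixes: [Z90.5]
  - id: urolithiasis
    name: Urolithiasis
    terms: [urolithiasis]
    icd10_prefixes: [N20]
  - id: congenital_renal_defect
    name: Congenital renal system defect
    terms: [congenital_renal_defect]
    icd10_prefixes: [Q61]
  - id: patent_foramen_ovale
    name: Patent foramen ovale
    terms: [patent_foramen_ovale]
    icd10_prefixes: [Q21.1]
  - id: head_trauma
    name: Trauma
    terms: [head_trauma]
    icd10_prefixes: [S06]
  - id: palliative_care
    name: Palliative care
    terms: [palliative_care]
    icd10_prefixes: [Z51.5]
  - id: alcohol_dependency
    name: Alcohol dependency
    terms: [alcohol_dependency]
    icd10_prefixes: [F10]
  - id: disseminated_cancer
    name: Disseminated cancer
    terms: [disseminated_cancer]
    icd10_prefixes: [C78, C79, C80]
  - id: blood_cancer
    name: Blood cancer
    terms: [leukemia, lymphoma]
    icd10_prefixes: [C81, C82, C83, C84, C85, C90, C91, C92, C93, C94, C95, C96]
  - id: chemotherapy
    name: Chemotherapy
    terms: [chemotherapy]
    icd10_prefixes: [Z51.1]

cohort_inclusion: {min_age: 18, max_age: 75}
cohort_exclusions:
  [palliative_care, alcohol_dependency, disseminated_cancer,
   blood_cancer, chemotherapy]

lab_rules:
  - {finding: reduced_egfr, analyte: egfr, op: "<", threshold: 60,
     unit: "mL/min/1.73m2"}
  - {finding: proteinuria_lab, analyte: urine_protein, op: ">", threshold: 150,
     unit: "mg/24h"}
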