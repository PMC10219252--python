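# Default English screening lexicon.
#
# Entries with a feature_id evidence one of the 13 scored clinical features
# in catalog.yaml; entries without a feature_id name confounder or
# cohort-exclusion conditions referenced by the catalog. Abbreviations are
# matched only when listed explicitly as synonyms (e.g. "pfo").

negation_cues: ["no", "not", "without", "denies", "denied", "negative", "absent", "never", "excluded"]
reset_tokens: [but, however, although, though, yet, except]
lemma_rules:
  - [omas, oma]
  - [urias, uria]
  - [pathies, pathy]
  - [esthesias, esthesia]
typo_correction: true
typo_min_len: 4

entries:
  # cardiovascular
  - term_id: hypertrophic_cardiomyopathy
    canonical: hypertrophic cardiomyopathy
    synonyms: [cardiomyopathy]
    feature_id: hypertrophic_cardiomyopathy
  - term_id: lv_hypertrophy
    canonical: left ventricular hypertrophy
    feature_id: hypertrophic_cardiomyopathy
  - term_id: myocardial_infarction
    canonical: myocardial infarction
    synonyms: [heart attack]
    feature_id: myocardial_infarction
  - term_id: arrhythmia
    canonical: arrhythmia
    synonyms: [cardiac arrhythmia, atrial fibrillation]
    feature_id: arrhythmia
  - term_id: conduction_abnormality
    canonical: conduction abnormality
    synonyms: [conduction disorder]
    feature_id: arrhythmia

  # kidney
  - term_id: renal_failure
    canonical: renal failure
    synonyms: [kidney failure, renal impairment, chronic kidney disease]
    feature_id: renal_failure
  - term_id: proteinuria
    canonical: proteinuria
    synonyms: [protein in urine, albuminuria]
    feature_id: proteinuria

  # skin
  - term_id: angiokeratoma
    canonical: angiokeratoma
    feature_id: angiokeratoma
  - term_id: hypohidrosis
    canonical: hypohidrosis
    synonyms: [impaired sweating]
    feature_id: hypohidrosis
  - term_id: heat_intolerance
    canonical: heat intolerance
    synonyms: [cold intolerance]
    feature_id: hypohidrosis

  # neurological
  - term_id: stroke
    canonical: stroke
    synonyms: [cerebral infarction]
    feature_id: stroke
  - term_id: tia
    canonical: transient ischemic attack
    feature_id: stroke
  - term_id: neuropathic_pain
    canonical: neuropathic pain
    synonyms: [burning pain in extremities, pain crisis, pain crises]
    feature_id: neuropathic_pain
  - term_id: acroparesthesia
    canonical: acroparesthesia
    feature_id: neuropathic_pain
  - term_id: hearing_loss
    canonical: hearing loss
    synonyms: [hearing impairment, tinnitus]
    feature_id: hearing_loss
  - term_id: abdominal_pain
    canonical: abdominal pain
    feature_id: gastrointestinal_symptoms
  - term_id: diarrhea
    canonical: diarrhea
    synonyms: [chronic diarrhea]
    feature_id: gastrointestinal_symptoms
  - term_id: nausea
    canonical: nausea
    feature_id: gastrointestinal_symptoms
  - term_id: recurrent_fever
    canonical: recurrent fever
    synonyms: [fever of unknown origin]
    feature_id: recurrent_fever

  # eye
  - term_id: cornea_verticillata
    canonical: cornea verticillata
    feature_id: cornea_verticillata
  - term_id: eye_fundus_lesions
    canonical: eye fundus lesions
    synonyms: [retinal vessel tortuosity]
    feature_id: cornea_verticillata

  # confounder / cohort-exclusion conditions (no feature)
  - term_id: amyloidosis
    canonical: amyloidosis
  - term_id: sarcoidosis
    canonical: sarcoidosis
  - term_id: nephropathy
    canonical: nephropathy
    synonyms: [diabetic nephropathy]
  - term_id: alport_syndrome
    canonical: alport syndrome
  - term_id: nephrectomy
    canonical: nephrectomy
    synonyms: [single kidney]
  - term_id: urolithiasis
    canonical: urolithiasis
    synonyms: [kidney stones]
  - term_id: congenital_renal_defect
    canonical: congenital renal defect
    synonyms: [renal agenesis]
  - term_id: patent_foramen_ovale
    canonical: patent foramen ovale
    synonyms: [pfo]
  - term_id: head_trauma
    canonical: head trauma
    synonyms: [traumatic brain injury]
  - term_id: palliative_care
    canonical: palliative care
  - term_id: alcohol_dependency
    canonical: alcohol dependency
    synonyms: [alcohol dependence, alcoholism]
  - term_id: disseminated_cancer
    canonical: disseminated cancer
    synonyms: [metastatic cancer]
  - term_id: leukemia
    canonical: leukemia
  - term_id: lymphoma
    canonical: lymphoma
  - term_id: chemotherapy
    canonical: chemotherapy
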