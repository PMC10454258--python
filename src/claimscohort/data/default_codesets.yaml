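# Default code content for the cohort algorithms and the nested
# cause-of-death suicide definitions.  Ranges like "T36-T65" are expanded
# to explicit prefixes at load time.  Codes are undotted ICD-10(-CM)
# prefixes; matching is dot-insensitive prefix comparison.

diagnosis_codesets:
  mdd: [F32, F33]
  si: [R45851]
  # Poisoning/self-injury attempt range plus transport/asphyxiation code T71.
  # With options.sa_intentional_only, T36-T65 matches are restricted to codes
  # whose 6th character marks intentional self-harm ("2").
  sa: [T36-T65, T71]
  bipolar_mania: [F30, F31]
  dementia: [F01, F02, F03, G30]
  psychosis: [F23, F28, F29]
  autism: [F84]
  schizophrenia_psychotic: [F20, F25]

cause_of_death_groups:
  accidental_poisoning: [X40-X44]
  intentional_self_poisoning: [X60-X69]
  intentional_self_harm: [X70-X84]
  undetermined_poisoning: [Y10-Y19]
  undetermined_accident: [Y20-Y34]
  sequelae_self_harm: [Y870]
  sequelae_undetermined: [Y872]
  sequelae_unspecified: [Y899]

suicide_definitions:
  broad:
    - accidental_poisoning
    - intentional_self_poisoning
    - intentional_self_harm
    - undetermined_poisoning
    - undetermined_accident
    - sequelae_self_harm
    - sequelae_undetermined
    - sequelae_unspecified
  # Excludes undetermined-intent groups; their sequelae (Y87.2) and sequelae
  # of unspecified external cause (Y89.9) are placed with the undetermined
  # exclusions.  Sequelae of intentional self-harm stay in all three.
  probable:
    - accidental_poisoning
    - intentional_self_poisoning
    - intentional_self_harm
    - sequelae_self_harm
  # Additionally excludes accidental poisoning.
  strict:
    - intentional_self_poisoning
    - intentional_self_harm
    - sequelae_self_harm

drug_classes:
  antidepressant:
    - sertraline
    - fluoxetine
    - citalopram
    - escitalopram
    - paroxetine
    - venlafaxine
    - desvenlafaxine
    - duloxetine
    - bupropion
    - mirtazapine
    - trazodone
    - vortioxetine
    - amitriptyline
    - nortriptyline
  atypical_antipsychotic:
    - quetiapine
    - aripiprazole
    - olanzapine
    - risperidone
    - lurasidone
    - ziprasidone
    - brexpiprazole
  antipsychotic_other:
    - haloperidol
    - chlorpromazine
  anxiolytic:
    - buspirone
    - hydroxyzine
  benzodiazepine:
    - alprazolam
    - lorazepam
    - clonazepam
    - diazepam
  other:
    - metformin
    - lisinopril
    - atorvastatin

# Miniature diagnosis-code -> comorbidity-category map standing in for the
# full AHRQ CCS grouper; user-replaceable with a complete mapping.
condition_categories:
  anxiety_disorders: [F40, F41]
  adhd_conduct_disruptive: [F90, F91]
  cerebrovascular_disease: [I60-I69]
  dementia: [F01, F02, F03, G30]
  epilepsy_convulsions: [G40, R56]
  headache_migraine: [G43, G44, R51]
  intracranial_injury: [S06]
  personality_disorders: [F60]
  psychosis: [F23, F28, F29]
  schizophrenia_psychotic: [F20, F25]
  substance_related: [F10-F19]
  suicide_self_injury: [R45851, T36-T65, T71, X71-X84]

options:
  sa_intentional_only: false
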