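# Default covariate registry for the two-arm pneumonia-style cohort schema.
#
# `in_propensity_model: true` marks the 34 pretreatment covariates that enter
# propensity-score estimation by default.  `hospital` is carried in the schema
# (and in balance summaries) but excluded from the default PS set; the
# microbiology columns are post-treatment-setting flags used only by the
# microbiologically-confirmed subgroup filter.
covariates:
  - {name: age, kind: continuous, unit: years, in_propensity_model: true}
  - {name: female_sex, kind: binary, in_propensity_model: true}
  - name: hospital
    kind: categorical
    levels: [site_a, site_b, site_c, site_d]
    in_propensity_model: false
  - {name: outpatient, kind: binary, in_propensity_model: true}
  - {name: prior_hospitalization, kind: binary, in_propensity_model: true}
  - {name: nursing_home, kind: binary, in_propensity_model: true}
  - {name: dialysis, kind: binary, in_propensity_model: true}
  - {name: diabetes, kind: binary, in_propensity_model: true}
  - {name: heart_failure, kind: binary, in_propensity_model: true}
  - {name: liver_disease, kind: binary, in_propensity_model: true}
  - {name: renal_disease, kind: binary, in_propensity_model: true}
  - {name: dementia, kind: binary, in_propensity_model: true}
  - {name: malignancy, kind: binary, in_propensity_model: true}
  - {name: asthma, kind: binary, in_propensity_model: true}
  - {name: copd_bronchiectasis, kind: binary, in_propensity_model: true}
  - {name: oral_steroids, kind: binary, in_propensity_model: true}
  - {name: antacids, kind: binary, in_propensity_model: true}
  - {name: sleeping_drugs, kind: binary, in_propensity_model: true}
  - {name: aspiration_episodes, kind: binary, in_propensity_model: true}
  - {name: preexisting_impaired_consciousness, kind: binary, in_propensity_model: true}
  - {name: neuromuscular_disease, kind: binary, in_propensity_model: true}
  - {name: device_insertion, kind: binary, in_propensity_model: true}
  - {name: cerebrovascular_disease, kind: binary, in_propensity_model: true}
  - {name: bedridden, kind: binary, in_propensity_model: true}
  - {name: impaired_consciousness, kind: binary, in_propensity_model: true}
  - {name: heart_rate, kind: continuous, unit: beats/min, in_propensity_model: true}
  - {name: respiratory_rate, kind: continuous, unit: breaths/min, in_propensity_model: true}
  - {name: systolic_bp, kind: continuous, unit: mmHg, in_propensity_model: true}
  - {name: body_temperature, kind: continuous, unit: degC, in_propensity_model: true}
  - {name: hematocrit, kind: continuous, unit: "%", in_propensity_model: true}
  - {name: bun, kind: continuous, unit: mg/dL, in_propensity_model: true}
  - {name: sodium, kind: continuous, unit: mEq/L, in_propensity_model: true}
  - {name: glucose, kind: continuous, unit: mg/dL, in_propensity_model: true}
  - {name: albumin, kind: continuous, unit: g/dL, in_propensity_model: true}
  - {name: pleural_effusion, kind: binary, in_propensity_model: true}
  # microbiology flags (subgroup filter inputs, never in the PS model)
  - {name: blood_culture_positive, kind: binary, in_propensity_model: false}
  - {name: pleural_culture_positive, kind: binary, in_propensity_model: false}
  - {name: sputum_quality, kind: binary, in_propensity_model: false}
  - {name: sputum_cfu, kind: continuous, unit: CFU/mL, in_propensity_model: false}
  - {name: sputum_semiquant, kind: continuous, unit: score, in_propensity_model: false}
  - {name: urinary_antigen_positive, kind: binary, in_propensity_model: false}
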