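# Default synthetic-cohort profile: ~2,784 patients, ~11% in the dual-therapy
# arm, confounded assignment (treated patients younger, more often
# outpatients, fewer aspiration-associated factors), null treatment effect on
# both terminal outcomes, and MAR missingness in the laboratory / vital-sign
# covariates.  All omitted keys fall back to the built-in defaults.
n: 2784
seed: 0
true_effect: 0.0
secondary_effect: 0.0
target_treated_fraction: 0.11
copula_rho: 0.15
max_followup_days: 45.0
outcome_mix:
  stable: 0.5
  deterioration: 0.2
  transfer: 0.3
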