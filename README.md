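# matchboot

Reusable pipeline for comparing two treatment strategies in an observational
cohort with missing data:

- **Cohort schema & CSV IO** — typed covariate registry (34 default
  propensity-model covariates plus site and microbiology columns), strict
  validation, empty-cell missing markers.
- **Synthetic cohort generator** — Gaussian-copula covariates, confounded
  treatment assignment (logistic), cause-specific exponential hazards for
  the competing terminal outcomes (recovery / death) with a configurable
  true treatment effect, routing of event-free patients to
  stable / deterioration / transfer, and MAR missingness.  A truth
  side-table enables parameter-recovery testing.
- **Multiple imputation by chained equations** — m chains x fixed
  iterations; Bayesian linear regression + predictive mean matching for
  continuous targets, logistic draws for binary/categorical targets; ridge
  fallback on separation; observed cells never altered.
- **Propensity-score matching** — per-dataset logistic PS, probabilities
  averaged across imputed datasets then logit-transformed; caliper =
  multiplier (0.05 default, 0.01 sensitivity) x SD of the logit score;
  greedy 1:1 nearest-neighbor matching without replacement; standardized
  mean difference balance tables (|SMD| < 0.1 flag).
- **Endpoints** — per-arm death/recovery frequencies with absolute
  differences, antibiotic duration, inpatient length of stay,
  Aalen-Johansen cumulative incidence curves, CURB-65 severity scores, and
  subgroup/sensitivity filters (CURB-65 >= 3, microbiologically confirmed,
  complete-case).
- **Bootstrap-within-MI confidence intervals** — B bootstrap replicates per
  imputed dataset with full re-estimation (PS fit, caliper, match,
  endpoints) inside every replicate; all replicate estimates pooled into a
  single distribution; point estimate = pooled median, 95% CI = 2.5th /
  97.5th type-7 percentiles.

## CLI

```bash
# full pipeline: simulate -> impute -> match -> analyze -> report
matchboot run-all --seed 7 --outdir out --fast

# stage by stage
matchboot simulate --n 2784 --seed 1 --out cohort.csv
matchboot impute --cohort cohort.csv --out imputed/ --m 50 --iterations 5 --seed 2
matchboot match --imputed-dir imputed/ --out match/ --caliper-multiplier 0.05
matchboot analyze --imputed-dir imputed/ --out endpoints.json --b 1000 --seed 3

# subgroups and sensitivity analyses
matchboot run-all --seed 7 --outdir out --subgroup severe --subgroup micro \
    --complete-case --caliper-multiplier 0.01
```

`run-all` accepts a YAML config (see `src/matchboot/configs/apsg_like.yaml`
for the default synthetic-cohort profile); `--fast` switches to the reduced
m=5 / B=50 test profile.  Every stage writes plain CSV/JSON artifacts into
the output directory, and an identical config + master seed reproduces the
endpoint JSON byte for byte.

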