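# neuromediate

Causal mediation analysis of a binary genetic exposure (APOE ε4 carriership)
on cognition and incident dementia through structural brain-imaging markers
(hippocampal volume, AD-signature cortical thickness, white matter
hyperintensities, cerebral microbleeds), packaged as a tested, reusable
pipeline.  Because the motivating cohort data are not public, the package
ships a synthetic cohort generator with an explicit data-generating process
and a Monte-Carlo counterfactual truth oracle, so every estimator can be
validated by parameter recovery.

## What's inside

| module | contents |
|---|---|
| `neuromediate.config` | `DGPConfig` and friends: full parameterization of the synthetic data-generating process |
| `neuromediate.synthetic` | `generate_cohort`, `counterfactual_oracle`, `inject_missingness` |
| `neuromediate.calibrated` | ready-made DGPs: analytic-truth simulations and a published-marginals cohort factory |
| `neuromediate.preprocess` | ln-WMH transform, Z-standardization, ≥2-microbleed dichotomy, cognition g-factor (first unrotated PC), chained-equations multiple imputation, age-equivalent conversion |
| `neuromediate.mediation` | regression-based natural-effect decomposition (TE/NDE/NIE/PM) with exposure–mediator interaction, for all four continuous/binary model combinations; rare-outcome odds-ratio approximation; subject-level percentile bootstrap; multiple-imputation pooling |
| `neuromediate.multimediation` | joint natural effects for 2–4 mediators by Monte-Carlo g-computation |
| `neuromediate.pipeline` | full study orchestration: preprocessing, 4 mediators × 2 outcomes grid, multi-mediator sets, sensitivity variants, deterministic reports |

## CLI

```bash
# synthetic cohort (built-in cohort-like DGP, or --config <yaml>)
neuromediate simulate --out cohort.csv --seed 1 --n 5510

# derived columns: hv_z, ct_ad_z, wmh_z (ln then Z), mb2, g factor
neuromediate preprocess --data cohort.csv --out prepared.csv --g-factor both

# single-mediator decomposition with bootstrap CIs
neuromediate mediate --data prepared.csv --outcome g --outcome-type continuous \
    --mediator hv_z --mediator-type continuous \
    --confounders age,sex,education,smoking,bmi,sbp,bp_med,nonhdl,lipid_med,diabetes,af,stroke,icv \
    --boot 1000 --seed 1 --out mediation.json

# joint mediator set
neuromediate multimediate --data prepared.csv --outcome g --outcome-type continuous \
    --mediators hv_z:continuous,mb2:binary --confounders age,sex --out joint.json

# full study (primary grid + sensitivity variants)
neuromediate pipeline --data cohort.csv --out-dir report/ --seed 1
```

Column conventions: exposure `apoe4` (0/1); mediators `hv` (ml), `ct_ad`
(mm), `wmh` (ml, >0), `mb_count` / `mb_lobar_count` (non-negative integers);
cognitive tests `stroop` (higher = worse), `wft`, `ldst`, `wlt15`, `ppb`;
outcomes `dementia` (0/1) with `dementia_time` (years) and
`dementia_subtype` (`AD`/`other`/`none`).

## Notes on the estimator

- Natural effects are computed from closed-form combinations of a mediator
  model (M ~ A + C) and an outcome model with interaction
  (Y ~ A + M + A·M + C), averaged over the empirical confounder
  distribution; `confounder_reference="fixed-values"` evaluates at
  confounder means instead.
- Binary outcomes use the rare-outcome odds-ratio approximation and are
  rejected above 10% prevalence unless explicitly overridden.
- Proportion mediated is NIE/TE on the difference scale and
  `OR_NDE·(OR_NIE−1)/(OR_NDE·OR_NIE−1)` on the odds-ratio scale; values
  are reported (with an instability flag) even when direct and indirect
  effects have opposite signs.
- Bootstrap inference resamples subjects and refits both models in every
  replicate; p-values come from the percentile distribution with a +1
  continuity correction.
- Multiple-mediator decompositions draw mediator vectors conditionally
  independent given exposure and confounders, with common random numbers
  across exposure levels.
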