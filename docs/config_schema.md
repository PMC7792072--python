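# Design-config schema

A design is a YAML (or JSON) mapping with the top-level keys below.  All
durations are years; all rates are per year.  `load_design` validates every
structural invariant and reports all violations at once; `save_design`
writes a file that `load_design` inverts exactly.

```yaml
name: flair                      # free-text identifier
accrual_rate: 250.0              # patients/year, pooled over centres
minimisation_random_element: 0.8 # p in (0.5, 1]
dropout: {prob: 0.05, horizon_years: 8.0}

arms:                            # >= 2 entries, unique names
  - name: FCR
    role: control                # control | experimental
    median_pfs: 4.5              # exponential median, years, > 0
    mrd_neg_prob: 0.10           # optional, [0, 1]

stages:                          # indices 1..K consecutive; consecutive
  - index: 1                     # stages share >= 1 control arm
    arms: [FCR, IR]              # all declared
    ratio: [1, 1]                # positive integers, one per arm
    exit:                        # when this stage ends, either:
      arm: IR                    #   cumulative recruitment trigger
      count: 316                 #   (optionally since_stage: n, default 1)
      # years: 2.5               #   or a calendar trigger

hypotheses:
  - label: ir-vs-fcr-pfs         # unique
    experimental_arm: IR         # both arms must be simultaneously
    control_arm: FCR             # active in >= 1 stage
    endpoint: time_to_event      # time_to_event | binary
    alpha_two_sided: 0.05
    power: 0.80
    target_hr: 0.75              # optional; must equal
    control_median: 4.5          #   control_median / experimental_median
    experimental_median: 6.0     #   when all three are given
    accrual_years: 4.0
    min_followup_years: 4.0
    dropout_prob: 0.05
    interim_fractions: [0.5, 1.0]  # strictly increasing, last = 1
    # binary endpoints instead use p_control / p_experimental

stratification:
  - {name: binet_stage, levels: [A_progressive, B_C]}
  - {name: centre, levels: 100}  # int shorthand: generated level labels
```

A stage's `exit` trigger with `since_stage: 2` counts recruitment to the
named arm from the start of stage 2 onwards — used to express "274 patients
concurrently randomised to FCR alongside I+V".
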