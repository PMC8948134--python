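# Calibrated by the package authors: as case4 but with slower family-support
# step-down and a longer maladaptive-behavior onset delay, deferring the
# tipping point to the fourth school transition.  Implementer calibration,
# not published estimates.
name: case6
description: >
  Tipping after the third transition: recovery from the first three school
  transitions, escalation after the transition at age 18.
params:
  initial_cv: 5.4
  initial_fs: 95.0
  cv_at: 0.6
  fs_at: 24.0
  family_response_delay: 0.5
  onset_mb_delay: 7.7
  ac_per_cv: 1.0
  mb_per_ac: 1.0
  effect_mb_gain: 0.8
  effect_fs_gain: 1.55
  fr_mb_weight: 0.02
  fr_ac_weight: 0.02
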