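# Calibrated by the package authors to exhibit the "recovery" pattern:
# each school transition shocks cognitive vulnerabilities, family support
# mobilizes, and the child returns near the pre-transition level.
# These values are implementer calibrations, not published estimates.
name: case1
description: >
  Quick recovery after every school transition: strong, fast family
  response and a modest maladaptive-behavior gain.
params:
  initial_cv: 10.0
  initial_fs: 25.0
  cv_at: 0.75
  fs_at: 0.75
  family_response_delay: 0.5
  onset_mb_delay: 2.0
  ac_per_cv: 1.0
  mb_per_ac: 1.0
  effect_mb_gain: 0.5
  effect_fs_gain: 0.9
  fr_mb_weight: 1.0
  fr_ac_weight: 1.0
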