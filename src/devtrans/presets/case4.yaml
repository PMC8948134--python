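# Calibrated by the package authors for a tipping point at the third school
# transition: high but slowly adjusting family support absorbs the first two
# shocks; maladaptive behaviors accumulate through a long onset delay, and
# by the third transition the reinforcing loop outruns the waning support.
# Implementer calibration, not published estimates.
name: case4
description: >
  Tipping after the second transition: full recovery from the first two
  school transitions, escalation from the third onward.
params:
  initial_cv: 13.5
  initial_fs: 95.0
  cv_at: 0.43
  fs_at: 22.0
  family_response_delay: 0.5
  onset_mb_delay: 3.8
  ac_per_cv: 1.0
  mb_per_ac: 1.0
  effect_mb_gain: 0.78
  effect_fs_gain: 1.48
  fr_mb_weight: 0.02
  fr_ac_weight: 0.02
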