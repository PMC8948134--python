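# Calibrated by the package authors: as case4 but with faster family-support
# step-down, so the tipping point arrives already at the second school
# transition.  Implementer calibration, not published estimates.
name: case5
description: >
  Tipping after the first transition: recovery from the kindergarten shock
  only, escalation from the middle-school transition onward.
params:
  initial_cv: 24.0
  initial_fs: 95.0
  cv_at: 0.45
  fs_at: 14.5
  family_response_delay: 0.5
  onset_mb_delay: 4.4
  ac_per_cv: 1.0
  mb_per_ac: 1.0
  effect_mb_gain: 1.0
  effect_fs_gain: 1.65
  fr_mb_weight: 0.02
  fr_ac_weight: 0.02
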