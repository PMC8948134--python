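# Calibrated by the package authors: cognitive vulnerabilities look stable
# before school entry while a large initial stock of family support holds
# them down; the support steps down toward its low indicated level, and the
# kindergarten transition launches an escalation that becomes chronic.
# Implementer calibration, not published estimates.
name: case3
description: >
  Post-transition escalation: stabilizing until the transition into school,
  then escalating without recovery to a chronic high level.
params:
  initial_cv: 4.0
  initial_fs: 95.0
  cv_at: 1.0
  fs_at: 5.0
  family_response_delay: 0.5
  onset_mb_delay: 2.0
  ac_per_cv: 1.0
  mb_per_ac: 1.0
  effect_mb_gain: 1.0
  effect_fs_gain: 1.4
  fr_mb_weight: 0.005
  fr_ac_weight: 0.005
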