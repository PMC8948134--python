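# Calibrated by the package authors to exhibit chronic escalation: a child
# predisposed to cognitive vulnerabilities whose family support rises with
# age but has almost no draining effect.  Implementer calibration, not
# published estimates.
name: case2
description: >
  Chronic escalation: high initial cognitive vulnerabilities and a strong
  maladaptive-behavior gain escalate to the maximum of 100; family support
  grows in response but its effect is too weak for recovery.
params:
  initial_cv: 35.0
  initial_fs: 5.0
  cv_at: 2.0
  fs_at: 2.0
  family_response_delay: 1.0
  onset_mb_delay: 1.5
  ac_per_cv: 1.0
  mb_per_ac: 1.0
  effect_mb_gain: 1.3
  effect_fs_gain: 0.05
  fr_mb_weight: 0.8
  fr_ac_weight: 0.8
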