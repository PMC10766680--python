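fpr_model:
  intercept: 6.46
  coef_t: 0.06
  coef_p: -0.01
  threshold_min: 6.6
  threshold_severe: 7.0
  threshold_extreme: 7.46
fpr_calibration:
  weight_mild: 1.0
  weight_severe: 2.0
  weight_extreme: 4.0
  scale: 0.01
  target_mean: 0.03
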