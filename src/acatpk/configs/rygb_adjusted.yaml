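name: rygb_adjusted
dose_mg: 1000.0
water_mL: 250.0
pk:
  body_weight_kg: 104.0
  renal_clearance_L_per_h_per_kg: 0.258
  volume_of_distribution_L_per_kg: 1.4
permeability:
  base_peff_cm_per_s: 1.0e-4
  multiplier: 1.0
  uniform: false
  colon_factor: 0.1
  segment_ratios:
    duodenum: 1.2
    jejunum: 1.0
    mid_SI: 0.75
    ileum: 0.5
physiology: rygb
settings:
  t_end_h: 96.0
  output_step_h: 0.05
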