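# Default engine configuration: every calibration constant and rule
# parameter of the nutrient-management engine. Edit a copy and pass it
# to the CLI with --config.
ty_uplift: 0.5
ty_min: 3.0
ty_max: 6.5
late_penalty_per_week: 0.25
n_calibration_anchors:
- [3.0, 57.0]
- [6.0, 123.0]
n_split_fractions: [0.3, 0.3, 0.4]
rie_p: 2.6
grain_p_fraction: 0.7
residue_biomass_fraction: 0.15
straw_p_fraction: 0.3
k_yield_gain_fraction: 0.15
rie_k: 14.5
k_recovery_efficiency: 0.44
k_basal_threshold: 33.0
pi_offset_days: 60
basal_window_map:
- [100.0, 5.0]
- [160.0, 21.0]
basal_deadline_min: 5
basal_deadline_max: 21
zinc_sulfate_rate: 25.0
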