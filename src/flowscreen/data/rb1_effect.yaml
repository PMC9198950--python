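target_gene: Rb1
bright_weight_factor: 1.0
mid_weight_factor: 0.737219
dim_weight_factor: 0.776686
intensity_shift: -0.221743
viability_factor: 1.0
ages:
- pup
- adult
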