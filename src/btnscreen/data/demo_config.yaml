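# Case-series demo: a small cohort with four diseased specimens whose
# neoplastic fractions match a published BTN2 case series (26.4 %, 44.4 %,
# 80 %, 91 %) plus healthy controls.
seed: 0
simulate:
  n_specimens: 24
  fixed_neoplastic_fractions: [0.264, 0.444, 0.8, 0.91]
n_genotyped_controls: 2
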