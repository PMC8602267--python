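# SYNTHETIC demonstration coefficients for the 6-SNP eye-colour
# prediction panel.  The model structure is the standard two-logit
# multinomial (blue-vs-brown, intermediate-vs-brown on effect-allele
# counts); these coefficient values are invented for simulation demos and
# tests and are NOT the published model parameters.
snps:
  - {name: rs12913832, effect_allele: C, other_allele: T}
  - {name: rs1800407, effect_allele: A, other_allele: G}
  - {name: rs12896399, effect_allele: T, other_allele: G}
  - {name: rs16891982, effect_allele: G, other_allele: C}
  - {name: rs1393350, effect_allele: A, other_allele: G}
  - {name: rs12203592, effect_allele: T, other_allele: C}
blue:
  intercept: -7.0
  slopes:
    rs12913832: 4.5
    rs1800407: -0.3
    rs12896399: 0.08
    rs16891982: 0.08
    rs1393350: 0.08
    rs12203592: 0.08
intermediate:
  intercept: -3.0
  slopes:
    rs12913832: 0.0
    rs1800407: 0.8
    rs12896399: 0.05
    rs16891982: 0.0
    rs1393350: 0.05
    rs12203592: 0.0
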