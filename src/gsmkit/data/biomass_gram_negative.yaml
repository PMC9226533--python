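# Baseline macromolecule mass fractions (g/gDW) for a gram-negative
# bacterium. Literature-order-of-magnitude values; review and adjust
# against measurements for the organism at hand before use.
organism_class: gram_negative
fractions:
  protein: 0.55
  rna: 0.16
  dna: 0.03
  lipid: 0.09
  carbohydrate: 0.12
  cofactor: 0.05
gam: 40.0
fixed_pools: {}
renormalize: false
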