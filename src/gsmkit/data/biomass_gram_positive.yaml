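# Baseline macromolecule mass fractions (g/gDW) for a gram-positive
# bacterium (thicker cell wall, higher carbohydrate share). Baselines
# only; review before use.
organism_class: gram_positive
fractions:
  protein: 0.52
  rna: 0.11
  dna: 0.03
  lipid: 0.08
  carbohydrate: 0.21
  cofactor: 0.05
gam: 35.0
fixed_pools: {}
renormalize: false
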