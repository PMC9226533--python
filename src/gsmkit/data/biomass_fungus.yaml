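# Baseline macromolecule mass fractions (g/gDW) for a fungus
# (cell-wall glucans/chitin raise the carbohydrate share). Baselines
# only; review before use.
organism_class: fungus
fractions:
  protein: 0.45
  rna: 0.08
  dna: 0.01
  lipid: 0.12
  carbohydrate: 0.30
  cofactor: 0.04
gam: 30.0
fixed_pools: {}
renormalize: false
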