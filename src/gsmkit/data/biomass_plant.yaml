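# Baseline macromolecule mass fractions (g/gDW) for plant tissue
# (cellulose-dominated). Baselines only; review before use.
organism_class: plant
fractions:
  protein: 0.30
  rna: 0.05
  dna: 0.01
  lipid: 0.10
  carbohydrate: 0.50
  cofactor: 0.04
gam: 30.0
fixed_pools: {}
renormalize: false
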