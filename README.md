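# gsmkit

A scriptable toolkit for reconstructing, refining and benchmarking
**genome-scale metabolic models** (GSMMs).

Reconstructing a curated GSMM is a months-long effort that starts from an
automatically assembled *draft*: the genome is annotated with enzymatic
functions, reactions are pulled in from reference knowledge, a biomass
objective is formulated, and the network is audited for gaps and
inconsistencies before manual curation begins.  `gsmkit` implements that
computational core as a library plus a CLI for people who build models of
bacteria, fungi and other organisms and want every step reproducible and
diffable — no GUI, no database server, no remote services.

## What it does

* **Enzyme annotation** — per-gene EC-number/product selection from tabular
  homology-search results (BLAST/Diamond-style), scored by
  `score = α·frequency + (1−α)·taxonomy`, where *frequency* is the fraction
  of a gene's hits carrying the label and *taxonomy* is the shared-lineage
  prefix similarity between the hit's source organism and the target;
  labels with `score ≥ τ` are committed.  An alternative *automatic
  workflow* adopts annotations from an ordered priority list of trusted
  taxa.
* **Template-based drafts** — reciprocal best hits (BBH) between the target
  and template proteomes decide which template reactions are inherited;
  boolean gene–protein–reaction (GPR) rules are rewritten onto target genes
  (strict policy: a complex is never asserted with missing subunits).
* **De novo drafts** — committed EC numbers pull reactions from a universal
  EC→reaction catalogue, with OR-of-genes GPRs.
* **Biomass formulation** — amino-acid and (deoxy)ribonucleotide
  compositions computed from the genome itself (optionally
  expression-weighted), converted to mmol/g coefficients via average
  residue masses, and assembled into polymerisation + biomass
  pseudo-reactions from an organism-class template (Gram±, fungus, plant).
* **Network audits** — elemental/charge balance, dead-end metabolites, and
  a sound topological blocked-reaction finder.
* **Compartment integration** — PSORTb/WoLF PSORT/LocTree3 report parsing
  with score thresholds, re-homing reactions by their genes' predicted
  compartments.
* **Benchmarking** — alias-mediated (MetaNetX-style hub table) comparison
  of draft vs curated reaction sets and case-insensitive locus-tag gene
  comparison, summarised as

  ```
  Precision = TP/(TP+FP)    Recall = TP/(TP+FN)    Ratio = TP/FP
  F1 = 2·P·R/(P+R)          Jaccard distance = 1 − TP/(TP+FP+FN)
  ```

  where TP are draft reactions with at least one alias in the curated
  model, FP draft reactions with none, and FN curated reactions missed by
  the draft (transport/exchange/sink/demand excluded on both sides).

Models are read and written as SBML level 3 (versions 1 and 2, `fbc`
package); genomes as GenBank/FASTA; everything else is TSV/YAML.

## Worked example

The package ships a deterministic synthetic-world generator with planted
ground truth, so the whole pipeline can be exercised without downloads:

```bash
gsmkit --seed 1 fixtures --out world
gsmkit draft-template --template world/template.xml \
    --fwd world/alignments_fwd.tsv --rev world/alignments_rev.tsv \
    --out draft.xml
gsmkit compare --draft draft.xml --curated world/template.xml \
    --aliases world/aliases.tsv --draft-ns template --curated-ns template
```

prints

```
fixture world -> world
8 ortholog pairs; draft: 5 reactions, 5 genes -> draft.xml
draft  entity     tp  fp  fn  precision  recall  ratio  f1      jaccard_distance
draft  genes      0   5   12  0.0        0.0     0.0    0.0     1.0
draft  reactions  5   0   4   1.0        0.556   inf    0.714   0.444
```

Reading the reaction row: the 12-gene fixture genome has 8 planted
orthologs to the 12-gene template, which resolve the GPRs of 5 of the 9
template reactions — so every inherited reaction is correct
(precision 1.0, ratio ∞) but 4 reactions are missed (recall 0.56,
Jaccard distance 0.44).  The gene row scores 0 because draft genes carry
the *target* organism's locus tags while the template carries its own —
exactly what happens when a draft of one organism is compared against a
curated model of a different one.

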