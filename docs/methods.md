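# Methods

This note documents the models, conventions and numerical choices behind
`gsmkit`, and what the synthetic fixtures do and do not demonstrate.

## Annotation scoring

Each gene's homology hits vote for EC numbers and (separately) product
names.  For a label ℓ among the hits of one gene:

* `frequency(ℓ)` — fraction of the gene's hits carrying ℓ;
* `taxonomy(ℓ)` — max over supporting hits of
  `shared_prefix(subject_lineage, target_lineage) / max(|subject|, |target|)`,
  i.e. how deep the hit's source organism agrees with the target organism's
  lineage, normalised by the longer lineage;
* `score(ℓ) = α·frequency + (1−α)·taxonomy`, committed when `score ≥ τ`.

Defaults `α = 0.5`, `τ = 0.5`; both are exposed in config and a grid-search
helper (`grid_search_parameters`) picks the pair maximising F1 against a
user-labelled gene sample.  Ties break by frequency, then lexicographic
label, making selection deterministic.  EC and product candidates are
scored independently (products are case-folded and whitespace-collapsed)
because the two selections are logically separable.  A `reviewed`
(curated-source) flag is parsed but does not enter the default score;
weighting by review status is a plausible extension that would need its
own calibration.

The *automatic workflow* bypasses scoring: hits are ranked by the index of
the first user-listed taxon they match (organism-name substring or exact
lineage rank, case-insensitive), then descending bitscore, then accession.
Genes matching no listed taxon fall back to the best-bitscore hit and are
flagged.

## Orthology and GPR propagation

Bidirectional best hits: after discarding hits below `min_bitscore`
(default 50) or above `max_evalue` (default 1e-5 — common practice
values), `(a, b)` is an ortholog pair iff `b` is `a`'s best surviving hit
and vice versa; best = max bitscore, ties by min e-value then lexicographic
subject id.

Template GPRs are rewritten leaf-by-leaf: each template gene becomes the
OR of its target orthologs.  Two policies handle unresolved leaves:

* **strict** (default): an AND node with any unresolved child is itself
  unresolved; OR nodes drop unresolved children.  Rationale: a complex
  should not be asserted when subunits are missing.
* **permissive**: AND nodes also drop unresolved children when at least
  one resolves.

Strict propagation is monotone in the ortholog map in the strong sense
(enlarging the map can only grow the rule's satisfying set, since the
expressions are monotone boolean functions and leaves are replaced by
supersets).  Permissive propagation is monotone only at the level of
resolvability — an enlarged map never turns a resolved rule absent, so a
reaction once inherited is never lost — but *not* at the satisfying-set
level: resolving a previously-dropped AND child adds a conjunct
(`g1 and g2` with only `g1→t1` mapped gives `t1`; adding `g2→t2` gives
`t1 and t2`).  Permissive output is always pointwise weaker than strict
output.  The acceptance suite asserts exactly these three properties.

Template reactions without any GPR ("orphans") are excluded by default,
since template inheritance is justified by homologous genes; multiple
templates are handled as repeated single-template runs whose drafts the
user unions.

## De novo assembly

A catalogue entry is included iff its EC set intersects the committed
annotation ECs with an exact four-field match; wildcard annotations
(`2.7.1.-`) match by prefix only when `expand_wildcards` is set, because
wildcard expansion inflates drafts non-conservatively.  The included
reaction's GPR is the OR of all supporting genes, and all metabolites are
homed in a single user-chosen compartment (compartment refinement comes
later in the workflow).

## Reaction classification

Metabolite ids carry a `_<compartment>` suffix (configurable regex).  A
reaction is an **exchange** iff it has exactly one metabolite and that
metabolite sits in the boundary compartment or the id bears the exchange
prefix (`EX_` by default); with one non-boundary metabolite it is a
**demand** (irreversible) or **sink** (reversible) — the two are not
structurally distinguishable any other way, so reversibility is the
committed convention, flagged here; a multi-compartment reaction in which
some base metabolite appears on both sides in different compartments is a
**transport**; everything else is **internal**.  Benchmarks exclude all
non-internal kinds from both sides, since boundary-reaction identifier
conversion across namespaces is unreliable.

## Biomass

Compositions use *average* (not monoisotopic) masses; the shipped monomer
table is overridable.  Residue mass = monomer mass − 18.0153 g/mol.
Frequencies come from uniform per-residue counting (per-CDS expression
weights optional; absent weights default to 1); coefficients are
`c_i = 1000·f_i / Σ_j f_j·residue_j` (mmol per g polymer), which enforces
`Σ c_i·residue_i = 1000` to machine precision.  DNA counts both strands
(so f_A = f_T and f_G = f_C exactly); RNA counts transcripts
single-stranded with T read as U.

Polymerisation byproducts are configurable: water per peptide bond for
protein, pyrophosphate per phosphodiester bond for nucleic acids (the
defaults mimic the usual pseudo-reaction chemistry; these reactions carry
`e-`-prefixed pseudo-species and are excluded from balance audits).
Macromolecule pools without a genome-derived composition (lipid,
carbohydrate, cofactor) receive an explicit placeholder source reaction
the curator must replace.  The shipped organism-class templates
(Gram-positive/negative, fungus, plant) are literature-order-of-magnitude
baselines with GAM defaults of 30–40 mmol ATP/gDW and must be reviewed
per organism.

## Audits

Balance checking parses Hill-notation formulas (no nested groups) and
reports signed products-minus-substrates element sums; reactions citing
any formula-less metabolite are reported "unknown" rather than guessed.

Dead ends and blocked reactions are purely topological: a metabolite is
never-produced if no admissible reaction direction creates it (reversible
reactions count both ways, exchanges as both); the blocked-reaction
finder iterates direction removal to a fixpoint.  This is **sound but
incomplete** relative to an LP/FVA check — every flagged reaction
provably carries zero steady-state flux (verified against a scipy-linprog
flux-variability oracle in the acceptance suite), but flux-coupled
infeasibilities that need rank arguments are not found.  The trade-off is
determinism and zero solver dependencies; a solver-backed checker can be
layered on top.

## Compartment integration

Localization dialects are normalised to [0, 1]: PSORTb long format by its
0–10 scale, LocTree3 by its 0–100 scale, WoLF PSORT k-NN votes by the
per-gene vote total, and a three-column generic TSV as the escape hatch
for format drift.  A gene adopts its top compartment when the normalised
score clears the threshold, else the default; each GPR-bearing reaction
moves to the majority compartment of its genes (ties and GPR-less
reactions keep the default/current home) and its non-boundary metabolites
are re-suffixed.  Integration is idempotent at fixed inputs.  Enzymes
predicted in several compartments get a single assignment (the top one);
duplicating reactions per compartment is deliberately out of scope.

## Benchmarking conventions

A draft reaction is TP if the union of curated-namespace ids reachable
through its alias hubs intersects the curated internal reaction set; it
counts once regardless of how many curated ids it matches.  FN are
curated internal reactions hit by no draft reaction — the consistent
completion of per-side TP/FP/FN definitions.  TP/FP ratio reports +inf
(text) / null (JSON) when FP = 0 and TP > 0.  Gene sets compare by
case-insensitive locus tag.

## Synthetic fixtures

All tests run on generated data: random codon CDSs, random sparse
stoichiometries, planted ortholog pairs and EC assignments with
alignment tables constructed so that the planted truth is the unique
correct answer (true hits score 200 with a near lineage; decoys score
lower or fail reciprocity).  One integer seed drives named, versioned
PRNG streams per artifact, making fixture directories byte-reproducible.
The fixtures are structural, not biological: passing tests demonstrate
algorithmic correctness (exact recovery of planted truths, metric
identities, soundness of audits), not annotation accuracy on real
genomes, where hit noise, paralogy and lineage errors dominate.

Problem sizes: the acceptance script uses a 30-gene, 24-reaction world,
50-reaction balance fixtures and 40 audit networks of ≤ 20 reactions —
small enough to re-run everywhere, large enough to exercise every code
path; the test suite covers 100-model/100-matrix sweeps for the
round-trip, BBH and soundness properties.

## SBML

Export targets level 3 versions 1 and 2 with the `fbc` v2 package:
bounds as shared flux-bound parameters, GPRs as gene-product association
trees, locus tags as gene-product labels.  Identifiers are sanitised to
SId with reversible `__<code>__` escapes so round trips are lossless.
Level 2 dialects and GenBank export are out of scope.  Workspaces are
plain directories (SBML + TSV + YAML manifest recording tool version and
seed) — diffable and clonable by copying, replacing any database-backed
project store.
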