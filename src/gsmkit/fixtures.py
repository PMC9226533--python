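"""Deterministic synthetic fixtures with planted ground truth.

Every generator is a pure function of an integer seed (one named PRNG
stream per artifact), so fixture directories are byte-reproducible.  The
fixtures are structural, not biological: sequences are random codons,
stoichiometries are random sparse vectors.  What is planted — ortholog
pairs, EC assignments, expected draft reaction sets, expected TP/FP/FN —
is recorded in a manifest so that pipeline output can be checked against
known truth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .annotation import ALIGNMENT_COLUMNS
from .benchmark import AliasTable, SetComparison
from .gpr import And, GeneRef, GPRNode, Or
from .model import (
    CatalogueEntry,
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionCatalogue,
)
from .sbml_io import write_sbml

# stream ids keep artifact randomness independent and stable
_STREAMS = {
    "sequences": 11, "catalogue": 12, "template": 13, "alignments": 14,
    "random_model": 15, "mutate": 16, "balanced": 17, "hits": 18,
}

TARGET_LINEAGE = (
    "Bacteria", "Synthobacterota", "Synthobacteria", "Synthobacterales",
    "Synthobacteraceae", "Closibacterium", "Closibacterium fictum",
)
NEAR_LINEAGE = TARGET_LINEAGE[:6] + ("Closibacterium relatum",)
FAR_LINEAGE = ("Bacteria", "Distantia", "Distantiae", "Distantiales",
               "Farbacteriaceae", "Farbacterium", "Farbacterium distans")
NEAR_ORGANISM = "Closibacterium relatum"
FAR_ORGANISM = "Farbacterium distans"

_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _ec(j: int) -> str:
    return f"{j % 6 + 1}.{j % 9 + 1}.{j % 13 + 1}.{j + 1}"


# -- sequences ---------------------------------------------------------------

def random_cds(rng: np.random.Generator, n_codons: int = 30) -> str:
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


# -- random fixture models ----------------------------------------------------

def random_model(
    seed: int,
    n_genes: int = 6,
    n_metabolites: int = 10,
    n_reactions: int = 8,
    model_id: Optional[str] = None,
    with_exchanges: bool = True,
) -> MetabolicModel:
    """A random but invariant-satisfying model with compartments ``c``/``e``,
    random GPR trees, mixed bounds and (sometimes missing) formulas."""
    rng = _rng(seed, "random_model")
    model = MetabolicModel(id=model_id or f"fixture_{seed}")
    model.compartments |= {"c", "e"}
    for i in range(n_genes):
        model.add_gene(Gene(locus_tag=f"g{i}"))
    met_ids = []
    for k in range(n_metabolites):
        formula = None
        if rng.random() < 0.8:
            formula = f"C{rng.integers(1, 7)}H{rng.integers(1, 13)}O{rng.integers(1, 7)}"
        charge = int(rng.integers(-1, 2)) if rng.random() < 0.5 else None
        met = Metabolite(id=f"met{k}_c", compartment="c", formula=formula, charge=charge)
        model.add_metabolite(met)
        met_ids.append(met.id)

    def random_gpr() -> Optional[GPRNode]:
        draw = rng.random()
        genes = [f"g{i}" for i in rng.choice(n_genes, size=min(3, n_genes), replace=False)]
        if draw < 0.25:
            return None
        if draw < 0.5:
            return GeneRef(genes[0])
        if draw < 0.75:
            return Or((GeneRef(genes[0]), GeneRef(genes[1])))
        return Or((And((GeneRef(genes[0]), GeneRef(genes[1]))), GeneRef(genes[2])))

    for j in range(n_reactions):
        k = int(rng.integers(2, 4))
        chosen = list(rng.choice(met_ids, size=k, replace=False))
        n_sub = max(1, k // 2)
        stoich = {}
        for idx, met_id in enumerate(chosen):
            coeff = float(rng.integers(1, 3))
            stoich[met_id] = -coeff if idx < n_sub else coeff
        reversible = bool(rng.random() < 0.4)
        model.add_reaction(Reaction(
            id=f"rxn{j}",
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=-1000.0 if reversible else 0.0,
            upper_bound=float(rng.choice([500.0, 1000.0])),
            gpr=random_gpr(),
            pathway=f"pathway{j % 3}" if rng.random() < 0.5 else None,
        ))
    if with_exchanges:
        n_ex = int(rng.integers(1, max(2, n_metabolites // 3)))
        for k in range(n_ex):
            base = f"met{k}"
            ext = Metabolite(id=f"{base}_e", compartment="e")
            model.add_metabolite(ext)
            model.add_reaction(Reaction(
                id=f"EX_{base}", stoichiometry={ext.id: -1.0},
                reversible=True, lower_bound=-1000.0, upper_bound=1000.0,
            ))
            model.add_reaction(Reaction(
                id=f"T_{base}",
                stoichiometry={ext.id: -1.0, f"{base}_c": 1.0},
                reversible=True, lower_bound=-1000.0, upper_bound=1000.0,
            ))
    return model


# -- toy world ----------------------------------------------------------------

def make_toy_world(
    seed: int, out_dir, n_genes: int = 12, n_reactions: int = 9
) -> Path:
    """Write a mutually consistent fixture directory.

    Contents: genome FASTA + GenBank (CDS per target gene), protein FASTA
    for target and template organisms, a reaction catalogue TSV, a
    template model SBML, forward/reverse alignment tables consistent with
    a planted ortholog map, an alias table linking catalogue and template
    namespaces, and a manifest recording every planted truth.
    """
    if n_genes < 1 or n_reactions < 1:
        raise ValueError("counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seq_rng = _rng(seed, "sequences")
    target_tags = [f"TGT_{i:04d}" for i in range(n_genes)]
    template_tags = [f"TPL_{i:04d}" for i in range(n_genes)]
    cds = {tag: random_cds(seq_rng) for tag in target_tags}
    proteins = {tag: str(Seq(s).translate()).rstrip("*") for tag, s in cds.items()}
    template_proteins = {
        tag: str(Seq(random_cds(seq_rng)).translate()).rstrip("*")
        for tag in template_tags
    }

    # planted orthologs: roughly two thirds of the genes, deterministically
    ortho_rng = _rng(seed, "alignments")
    n_orth = max(1, (2 * n_genes) // 3)
    orth_idx = sorted(ortho_rng.choice(n_genes, size=n_orth, replace=False).tolist())
    orthologs = [(target_tags[i], template_tags[i]) for i in orth_idx]

    # planted EC per target gene, drawn from the catalogue's EC space
    gene_ec = {target_tags[i]: _ec(i % n_reactions) for i in range(n_genes)}

    _write_genome(out_dir, cds, target_tags)
    _write_catalogue(out_dir, seed, n_reactions)
    template = _build_template(seed, template_tags, n_reactions, n_genes)
    write_sbml(template, out_dir / "template.xml", "3.1")
    _write_alignments(out_dir, seed, target_tags, template_tags, orth_idx, gene_ec)
    _write_aliases(out_dir, n_reactions)

    expected_template_draft = sorted(
        rid for rid, rxn in template.reactions.items()
        if rxn.gpr is not None and _resolvable(rxn.gpr, {b for _, b in orthologs})
    )
    annotated_ecs = set(gene_ec.values())
    expected_denovo = sorted(
        f"CRX_{j:04d}" for j in range(n_reactions) if _ec(j) in annotated_ecs
    )

    manifest = {
        "seed": int(seed),
        "n_genes": int(n_genes),
        "n_reactions": int(n_reactions),
        "target_lineage": list(TARGET_LINEAGE),
        "orthologs": [list(p) for p in orthologs],
        "gene_ec": dict(sorted(gene_ec.items())),
        "expected_template_draft": expected_template_draft,
        "expected_denovo": expected_denovo,
        "files": {
            "genome_fasta": "genome.fasta",
            "genome_genbank": "genome.gb",
            "proteins_fasta": "proteins.fasta",
            "catalogue": "catalogue.tsv",
            "template_sbml": "template.xml",
            "alignments_forward": "alignments_fwd.tsv",
            "alignments_reverse": "alignments_rev.tsv",
            "aliases": "aliases.tsv",
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    # template proteome, handy for running external aligners on the fixture
    _write_fasta(out_dir / "template_proteins.fasta", template_proteins)
    _write_fasta(out_dir / "proteins.fasta", proteins)
    return out_dir


def _resolvable(rule: GPRNode, mapped_template_genes: Set[str]) -> bool:
    """Strict-policy resolvability, restated independently of propagate_gpr."""
    if isinstance(rule, GeneRef):
        return rule.gene in mapped_template_genes
    if isinstance(rule, And):
        return all(_resolvable(c, mapped_template_genes) for c in rule.children)
    return any(_resolvable(c, mapped_template_genes) for c in rule.children)


def _write_fasta(path: Path, sequences: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


def _write_genome(out_dir: Path, cds: Dict[str, str], order: Sequence[str]) -> None:
    genome = "".join(cds[tag] for tag in order)
    _write_fasta(out_dir / "genome.fasta", {"chromosome": genome})
    record = SeqRecord(Seq(genome), id="chromosome", name="chromosome",
                       description="synthetic fixture genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["date"] = "01-JAN-2000"
    record.annotations["topology"] = "linear"
    offset = 0
    for tag in order:
        length = len(cds[tag])
        feature = SeqFeature(
            FeatureLocation(offset, offset + length, strand=1), type="CDS",
            qualifiers={"locus_tag": [tag]},
        )
        record.features.append(feature)
        offset += length
    from Bio import SeqIO

    SeqIO.write([record], str(out_dir / "genome.gb"), "genbank")


def _write_catalogue(out_dir: Path, seed: int, n_reactions: int) -> None:
    cat = build_catalogue(seed, n_reactions)
    cat.write_tsv(out_dir / "catalogue.tsv")


def build_catalogue(seed: int, n_reactions: int) -> ReactionCatalogue:
    """The toy world's universal catalogue: compartment-free reactions with
    one EC each and a small shared metabolite pool."""
    rng = _rng(seed, "catalogue")
    n_mets = n_reactions + 4
    cat = ReactionCatalogue()
    for j in range(n_reactions):
        pool = rng.choice(n_mets, size=4, replace=False)
        stoich = {
            f"cm{pool[0]}": -1.0, f"cm{pool[1]}": -float(rng.integers(1, 3)),
            f"cm{pool[2]}": 1.0, f"cm{pool[3]}": float(rng.integers(1, 3)),
        }
        cat.add(CatalogueEntry(
            id=f"CRX_{j:04d}", name=f"catalogue reaction {j}",
            stoichiometry=stoich, reversible=bool(j % 2),
            ec_numbers={_ec(j)}, pathway=f"pathway{j % 3}",
        ))
    return cat


def _build_template(
    seed: int, template_tags: Sequence[str], n_reactions: int, n_genes: int
) -> MetabolicModel:
    """Template model: the catalogue reactions homed in ``c`` under template
    ids TRX_*, with simple single/OR/AND GPRs over template genes."""
    cat = build_catalogue(seed, n_reactions)
    model = MetabolicModel(id="template", namespace="template")
    model.compartments |= {"c", "e"}
    for tag in template_tags:
        model.add_gene(Gene(locus_tag=tag))
    met_ids = sorted({
        f"{m}_c" for entry in cat.entries.values() for m in entry.stoichiometry
    })
    for mid in met_ids:
        model.add_metabolite(Metabolite(id=mid, compartment="c"))
    for j in range(n_reactions):
        entry = cat.entries[f"CRX_{j:04d}"]
        g1 = template_tags[j % n_genes]
        g2 = template_tags[(j + 1) % n_genes]
        if j % 3 == 0 or n_genes == 1:
            gpr: GPRNode = GeneRef(g1)
        elif j % 3 == 1:
            gpr = Or((GeneRef(g1), GeneRef(g2)))
        else:
            gpr = And((GeneRef(g1), GeneRef(g2)))
        model.add_reaction(Reaction(
            id=f"TRX_{j:04d}", name=entry.name,
            stoichiometry={f"{m}_c": c for m, c in entry.stoichiometry.items()},
            reversible=entry.reversible,
            lower_bound=-1000.0 if entry.reversible else 0.0,
            upper_bound=1000.0, gpr=gpr, pathway=entry.pathway,
        ))
    return model


def toy_template(seed: int, n_genes: int = 8, n_reactions: int = 10) -> MetabolicModel:
    """A standalone template model in which every reaction carries a GPR."""
    tags = [f"TPL_{i:04d}" for i in range(n_genes)]
    return _build_template(seed, tags, n_reactions, n_genes)


def _hit_row(query, subject, bitscore, evalue, organism, lineage, ec, product):
    return {
        "query": query, "subject": subject, "identity": 85.0,
        "alignment_length": 90, "mismatches": 10, "gap_opens": 0,
        "q_start": 1, "q_end": 90, "s_start": 1, "s_end": 90,
        "evalue": evalue, "bitscore": bitscore,
        "subject_organism": organism, "subject_lineage": ";".join(lineage),
        "subject_ec": ec, "subject_product": product, "reviewed": 1,
    }


def _write_alignments(
    out_dir: Path, seed: int, target_tags: Sequence[str],
    template_tags: Sequence[str], orth_idx: Sequence[int],
    gene_ec: Dict[str, str],
) -> None:
    n = len(target_tags)
    orth = set(orth_idx)
    fwd_rows: List[dict] = []
    rev_rows: List[dict] = []
    for i in range(n):
        tgt, tpl = target_tags[i], template_tags[i]
        true_ec = gene_ec[tgt]
        decoy_ec = gene_ec[target_tags[(i + 1) % n]]
        if i in orth:
            # reciprocal best pair, plus a weaker decoy in each direction
            fwd_rows.append(_hit_row(tgt, tpl, 200.0, 1e-60, NEAR_ORGANISM,
                                     NEAR_LINEAGE, true_ec, f"enzyme {true_ec}"))
            fwd_rows.append(_hit_row(tgt, template_tags[(i + 1) % n], 80.0, 1e-20,
                                     FAR_ORGANISM, FAR_LINEAGE, decoy_ec,
                                     f"enzyme {decoy_ec}"))
            rev_rows.append(_hit_row(tpl, tgt, 195.0, 1e-58, NEAR_ORGANISM,
                                     NEAR_LINEAGE, true_ec, f"enzyme {true_ec}"))
            rev_rows.append(_hit_row(tpl, target_tags[(i + 1) % n], 75.0, 1e-18,
                                     FAR_ORGANISM, FAR_LINEAGE, decoy_ec,
                                     f"enzyme {decoy_ec}"))
        else:
            # best forward hit points at an orthologous template gene whose
            # own best hit is elsewhere: reciprocity fails by construction
            other = template_tags[min(orth_idx)] if orth_idx else tpl
            fwd_rows.append(_hit_row(tgt, other, 100.0, 1e-30, NEAR_ORGANISM,
                                     NEAR_LINEAGE, true_ec, f"enzyme {true_ec}"))
            fwd_rows.append(_hit_row(tgt, template_tags[(i + 1) % n], 40.0, 1e-4,
                                     FAR_ORGANISM, FAR_LINEAGE, decoy_ec,
                                     f"enzyme {decoy_ec}"))
    pd.DataFrame(fwd_rows, columns=ALIGNMENT_COLUMNS + ["reviewed"]).to_csv(
        out_dir / "alignments_fwd.tsv", sep="\t", index=False
    )
    pd.DataFrame(rev_rows, columns=ALIGNMENT_COLUMNS + ["reviewed"]).to_csv(
        out_dir / "alignments_rev.tsv", sep="\t", index=False
    )


def _write_aliases(out_dir: Path, n_reactions: int) -> None:
    table = AliasTable()
    for j in range(n_reactions):
        hub = f"HUB_{j:04d}"
        table.add("catalogue", f"CRX_{j:04d}", hub)
        table.add("template", f"TRX_{j:04d}", hub)
    table.write_tsv(out_dir / "aliases.tsv")


def load_manifest(world_dir) -> dict:
    with open(Path(world_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)


# -- mutation with known truth ------------------------------------------------

def mutate_model(
    model: MetabolicModel, n_remove: int, n_add: int, seed: int
) -> Tuple[MetabolicModel, SetComparison]:
    """Remove internal reactions and add novel ones, returning the expected
    comparison against the original (tp = kept internals, fp = added,
    fn = removed)."""
    internal = sorted(model.internal_reactions())
    if n_remove > len(internal):
        raise ValueError(
            f"cannot remove {n_remove} of {len(internal)} internal reactions"
        )
    rng = _rng(seed, "mutate")
    removed = set(
        rng.choice(internal, size=n_remove, replace=False).tolist()
    ) if n_remove else set()
    mutated = model.copy()
    for rid in removed:
        del mutated.reactions[rid]

    comp_mets: Dict[str, List[str]] = {}
    for met in mutated.metabolites.values():
        if not met.pseudo and met.compartment != mutated.boundary_compartment:
            comp_mets.setdefault(met.compartment, []).append(met.id)
    pool_comp = max(comp_mets, key=lambda c: len(comp_mets[c]))
    pool = sorted(comp_mets[pool_comp])
    if len(pool) < 2 and n_add:
        raise ValueError("model too small to add novel internal reactions")
    added = []
    for k in range(n_add):
        a, b = rng.choice(pool, size=2, replace=False)
        rid = f"NOVEL_{k:04d}"
        mutated.add_reaction(Reaction(
            id=rid, stoichiometry={a: -1.0, b: 1.0}, reversible=False,
        ))
        added.append(rid)
    expected = SetComparison(
        tp_items=set(internal) - removed,
        fp_items=set(added),
        fn_items=removed,
    )
    return mutated, expected


# -- balanced networks for the balance auditor --------------------------------

def make_balanced_model(seed: int, n_reactions: int = 50) -> MetabolicModel:
    """A model whose internal reactions are elementally balanced by
    construction: each product's formula is the element-sum of its
    substrates."""
    rng = _rng(seed, "balanced")
    model = MetabolicModel(id=f"balanced_{seed}")
    model.compartments.add("c")
    elements = ("C", "H", "O", "N")

    def formula_of(counts: Dict[str, int]) -> str:
        return "".join(f"{e}{counts[e]}" for e in elements if counts.get(e, 0) > 0)

    counts: Dict[str, Dict[str, int]] = {}
    for k in range(n_reactions + 2):
        c = {e: int(rng.integers(1, 5)) for e in elements}
        mid = f"b{k}_c"
        counts[mid] = c
        model.add_metabolite(Metabolite(id=mid, compartment="c",
                                        formula=formula_of(c), charge=0))
    met_ids = sorted(counts)
    for j in range(n_reactions):
        a, b = rng.choice(met_ids, size=2, replace=False)
        total = {e: counts[a][e] + counts[b][e] for e in elements}
        pid = f"p{j}_c"
        counts[pid] = total
        model.add_metabolite(Metabolite(id=pid, compartment="c",
                                        formula=formula_of(total), charge=0))
        model.add_reaction(Reaction(id=f"brx{j}", stoichiometry={a: -1.0, b: -1.0, pid: 1.0}))
    return model


def inject_imbalance(
    model: MetabolicModel, seed: int, reaction_ids: Optional[Sequence[str]] = None
) -> Dict[str, Tuple[str, int]]:
    """Perturb one product formula per listed reaction by a single element.

    Returns {reaction id: (element, injected delta)} where the delta is
    the resulting products-minus-substrates imbalance.  Mutates the model
    in place.
    """
    from .refinement import parse_formula

    rng = _rng(seed, "balanced")
    if reaction_ids is None:
        reaction_ids = sorted(model.reactions)
    injected: Dict[str, Tuple[str, int]] = {}
    for rid in reaction_ids:
        rxn = model.reactions[rid]
        products = sorted(rxn.products())
        if not products:
            continue
        met = model.metabolites[products[0]]
        counts = parse_formula(met.formula)
        element = str(rng.choice(sorted(counts)))
        delta = int(rng.choice([-1, 1]))
        if counts[element] + delta <= 0:
            delta = 1
        counts[element] += delta
        met.formula = "".join(
            f"{e}{n}" for e, n in sorted(counts.items()) if n > 0
        )
        coeff = rxn.stoichiometry[met.id]
        injected[rid] = (element, int(delta * coeff))
    return injected


__all__ = [
    "make_toy_world", "load_manifest", "mutate_model", "random_model",
    "make_balanced_model", "inject_imbalance", "build_catalogue", "random_cds",
    "toy_template",
    "TARGET_LINEAGE", "NEAR_LINEAGE", "FAR_LINEAGE",
]
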