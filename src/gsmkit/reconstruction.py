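"""Draft model assembly.

Two routes are provided:

* **template-based** — reciprocal-best-hit orthologs between the target
  genome and a curated template model decide which template reactions are
  inherited; the template's GPR rules are rewritten onto target genes.
* **de novo** — committed EC annotations pull reactions out of a
  universal reaction catalogue, with an OR-of-genes GPR per reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .annotation import AlignmentHit, AnnotationTable
from .gpr import And, GeneRef, GPRNode, Or, simplify
from .model import (
    CatalogueEntry,
    Gene,
    IntegrityError,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionCatalogue,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_BITSCORE = 50.0
DEFAULT_MAX_EVALUE = 1e-5


@dataclass
class OrthologMap:
    """Reciprocal best-hit pairs (target gene, template gene) with the
    supporting bitscores in each direction."""

    pairs: Set[Tuple[str, str]] = field(default_factory=set)
    forward_bitscore: Dict[Tuple[str, str], float] = field(default_factory=dict)
    reverse_bitscore: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def targets_of(self, template_gene: str) -> Set[str]:
        return {t for t, g in self.pairs if g == template_gene}

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, genes: Iterable[str]) -> "OrthologMap":
        pairs = {(g, g) for g in genes}
        return cls(pairs=pairs,
                   forward_bitscore={p: float("inf") for p in pairs},
                   reverse_bitscore={p: float("inf") for p in pairs})


def _best_hits(hits: Sequence[AlignmentHit], min_bitscore: float,
               max_evalue: float) -> Dict[str, AlignmentHit]:
    """Per query, the surviving hit with max bitscore (ties: min e-value,
    then lexicographic subject id)."""
    best: Dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.bitscore < min_bitscore or hit.evalue > max_evalue:
            continue
        cur = best.get(hit.query)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject) < (
            -cur.bitscore, cur.evalue, cur.subject
        ):
            best[hit.query] = hit
    return best


def bidirectional_best_hits(
    hits_target_to_template: Sequence[AlignmentHit],
    hits_template_to_target: Sequence[AlignmentHit],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> OrthologMap:
    """Reciprocal best hits between two proteomes.

    (a, b) is kept iff, after filtering, b is a's best template hit and a
    is b's best target hit.
    """
    fwd = _best_hits(hits_target_to_template, min_bitscore, max_evalue)
    rev = _best_hits(hits_template_to_target, min_bitscore, max_evalue)
    out = OrthologMap()
    for target, hit in fwd.items():
        template = hit.subject
        back = rev.get(template)
        if back is not None and back.subject == target:
            out.pairs.add((target, template))
            out.forward_bitscore[(target, template)] = hit.bitscore
            out.reverse_bitscore[(target, template)] = back.bitscore
    return out


# -- GPR propagation ----------------------------------------------------------

def propagate_gpr(
    rule: GPRNode, orthologs: OrthologMap, policy: str = "strict"
) -> Optional[GPRNode]:
    """Rewrite a template GPR onto target genes.

    Each template-gene leaf becomes the OR of its target orthologs.
    ``strict``: an AND node with any unresolved child is itself
    unresolved (a complex is not asserted with missing subunits); OR
    nodes drop unresolved children.  ``permissive``: AND nodes also drop
    unresolved children as long as at least one child resolves.  Returns
    ``None`` when nothing resolves.
    """
    if policy not in {"strict", "permissive"}:
        raise ValueError(f"unknown propagation policy {policy!r}")

    def visit(node: GPRNode) -> Optional[GPRNode]:
        if isinstance(node, GeneRef):
            targets = sorted(orthologs.targets_of(node.gene))
            if not targets:
                return None
            if len(targets) == 1:
                return GeneRef(targets[0])
            return Or(tuple(GeneRef(t) for t in targets))
        resolved = [v for v in (visit(c) for c in node.children) if v is not None]
        if not resolved:
            return None
        if isinstance(node, And):
            if policy == "strict" and len(resolved) != len(node.children):
                return None
            return resolved[0] if len(resolved) == 1 else And(tuple(resolved))
        return resolved[0] if len(resolved) == 1 else Or(tuple(resolved))

    out = visit(rule)
    return simplify(out) if out is not None else None


def reconstruct_from_template(
    template: MetabolicModel,
    orthologs: OrthologMap,
    policy: str = "strict",
    include_orphans: bool = False,
    draft_id: Optional[str] = None,
) -> MetabolicModel:
    """Inherit template reactions whose GPR survives ortholog propagation.

    Reactions without any GPR in the template ("orphans") are copied only
    when ``include_orphans`` is set.  Metabolites and compartments are
    pruned to those referenced by inherited reactions; the draft's gene
    set is exactly the target genes cited by the propagated rules.
    """
    problems = template.validate()
    if problems:
        raise IntegrityError("template model invalid:\n  " + "\n  ".join(problems))
    draft = MetabolicModel(
        id=draft_id or f"{template.id}_draft",
        namespace=template.namespace,
        boundary_compartment=template.boundary_compartment,
        exchange_prefix=template.exchange_prefix,
    )
    kept: List[Tuple[Reaction, Optional[GPRNode]]] = []
    for rxn in template.reactions.values():
        if rxn.gpr is None:
            if include_orphans:
                kept.append((rxn, None))
            continue
        propagated = propagate_gpr(rxn.gpr, orthologs, policy)
        if propagated is not None:
            kept.append((rxn, propagated))

    genes: Set[str] = set()
    for _, gpr in kept:
        if gpr is not None:
            genes |= gpr.genes()
    for tag in sorted(genes):
        draft.add_gene(Gene(locus_tag=tag))
    met_ids = {m for rxn, _ in kept for m in rxn.stoichiometry}
    for mid in sorted(met_ids):
        met = template.metabolites[mid]
        draft.add_metabolite(Metabolite(
            id=met.id, name=met.name, compartment=met.compartment,
            formula=met.formula, charge=met.charge,
        ))
    for rxn, gpr in kept:
        draft.add_reaction(Reaction(
            id=rxn.id, name=rxn.name, stoichiometry=dict(rxn.stoichiometry),
            reversible=rxn.reversible, lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound, gpr=gpr, pathway=rxn.pathway,
        ))
    return draft


# -- de novo assembly ---------------------------------------------------------

def _ec_matches(annotated_ec: str, catalogue_ec: str, expand_wildcards: bool) -> bool:
    if annotated_ec == catalogue_ec:
        return True
    if expand_wildcards and annotated_ec.endswith("-"):
        prefix = annotated_ec.rstrip("-")
        return catalogue_ec.startswith(prefix)
    return False


def assemble_denovo(
    annotations: AnnotationTable,
    catalogue: ReactionCatalogue,
    compartment: str = "c",
    expand_wildcards: bool = False,
    draft_id: str = "denovo_draft",
    namespace: str = "catalogue",
) -> MetabolicModel:
    """Build a draft by pulling catalogue reactions for every annotated EC.

    A catalogue entry is included iff its EC set intersects the committed
    annotation EC set (exact four-field match unless wildcard expansion
    is enabled); the reaction's GPR is the OR of all genes annotated with
    a matching EC.  All metabolites are homed in ``compartment``.
    """
    gene_ecs = annotations.annotated_ecs()
    draft = MetabolicModel(id=draft_id, namespace=namespace)
    draft.compartments.add(compartment)

    included: List[Tuple[CatalogueEntry, List[str]]] = []
    for entry in sorted(catalogue.entries.values(), key=lambda e: e.id):
        supporting = sorted(
            tag for tag, ecs in gene_ecs.items()
            if any(
                _ec_matches(a_ec, c_ec, expand_wildcards)
                for a_ec in ecs for c_ec in entry.ec_numbers
            )
        )
        if supporting:
            included.append((entry, supporting))

    for _, supporting in included:
        for tag in supporting:
            if tag not in draft.genes:
                ann = annotations.entries[tag]
                draft.add_gene(Gene(locus_tag=tag, product=ann.product,
                                    ec_numbers=set(ann.ec_numbers)))
    met_ids = sorted({
        f"{m}_{compartment}" for entry, _ in included for m in entry.stoichiometry
    })
    for mid in met_ids:
        draft.add_metabolite(Metabolite(id=mid, compartment=compartment))
    for entry, supporting in included:
        gpr: GPRNode
        if len(supporting) == 1:
            gpr = GeneRef(supporting[0])
        else:
            gpr = Or(tuple(GeneRef(t) for t in supporting))
        stoich = {f"{m}_{compartment}": c for m, c in entry.stoichiometry.items()}
        draft.add_reaction(Reaction(
            id=entry.id, name=entry.name, stoichiometry=stoich,
            reversible=entry.reversible,
            lower_bound=-1000.0 if entry.reversible else 0.0,
            upper_bound=1000.0,
            gpr=gpr, pathway=entry.pathway,
        ))
    return draft


def build_complex_gprs(
    model: MetabolicModel, subunit_table: Dict[str, List[Set[str]]]
) -> MetabolicModel:
    """Rewrite listed reactions' GPRs as OR-of-isoforms, AND-of-subunits.

    ``subunit_table`` maps reaction id -> list of gene sets, one set per
    isoform (an isoform with several genes is a complex).  Unlisted
    reactions are untouched.
    """
    out = model.copy()
    for rxn_id, isoforms in subunit_table.items():
        if rxn_id not in out.reactions:
            raise IntegrityError(f"subunit table cites unknown reaction {rxn_id}")
        for genes in isoforms:
            unknown = sorted(set(genes) - set(out.genes))
            if unknown:
                raise IntegrityError(
                    f"subunit table for {rxn_id} cites unknown genes {unknown}"
                )
        terms: List[GPRNode] = []
        for genes in isoforms:
            members = sorted(genes)
            if len(members) == 1:
                terms.append(GeneRef(members[0]))
            else:
                terms.append(And(tuple(GeneRef(g) for g in members)))
        if not terms:
            continue
        out.reactions[rxn_id].gpr = simplify(
            terms[0] if len(terms) == 1 else Or(tuple(terms))
        )
    return out


__all__ = [
    "OrthologMap", "bidirectional_best_hits", "propagate_gpr",
    "reconstruct_from_template", "assemble_denovo", "build_complex_gprs",
    "DEFAULT_MIN_BITSCORE", "DEFAULT_MAX_EVALUE",
]
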