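"""Core domain types for genome-scale metabolic models.

The container here is deliberately plain: keyed collections of genes,
metabolites and reactions plus a compartment set, with referential
integrity checked by :meth:`MetabolicModel.validate`.  Heavy analysis
(flux simulation, gap filling) is out of scope; the container exists to
carry drafts, templates and curated models through reconstruction,
refinement and benchmarking.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Set, Tuple

from .gpr import GPRNode, gpr_equal


class IntegrityError(ValueError):
    """A model (or an edit to one) violates referential integrity."""


class ReactionKind(str, Enum):
    INTERNAL = "internal"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    SINK = "sink"
    DEMAND = "demand"


#: reaction kinds excluded from draft-vs-curated comparisons
BOUNDARY_KINDS = frozenset(
    {ReactionKind.TRANSPORT, ReactionKind.EXCHANGE, ReactionKind.SINK, ReactionKind.DEMAND}
)

#: default regex capturing the compartment suffix of a metabolite id
COMPARTMENT_SUFFIX_RE = re.compile(r"^(?P<base>.+?)_(?P<comp>[A-Za-z0-9]+)$")

#: default id prefix marking exchange reactions
EXCHANGE_PREFIX = "EX_"

#: metabolite-id prefix marking biomass pseudo-species (skipped by audits)
PSEUDO_PREFIX = "e-"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def base_id(self, suffix_re: re.Pattern = COMPARTMENT_SUFFIX_RE) -> str:
        """Metabolite id stripped of its compartment suffix."""
        m = suffix_re.match(self.id)
        return m.group("base") if m else self.id

    @property
    def pseudo(self) -> bool:
        return self.id.startswith(PSEUDO_PREFIX) or self.base_id().startswith(PSEUDO_PREFIX)


@dataclass
class Gene:
    locus_tag: str
    product: Optional[str] = None
    ec_numbers: Set[str] = field(default_factory=set)


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]  # metabolite id -> signed coefficient
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GPRNode] = None
    pathway: Optional[str] = None
    name: str = ""

    def substrates(self) -> Dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> Dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def validate(self) -> None:
        if not self.stoichiometry:
            raise IntegrityError(f"reaction {self.id}: empty stoichiometry")
        zeros = [m for m, c in self.stoichiometry.items() if c == 0]
        if zeros:
            raise IntegrityError(f"reaction {self.id}: zero coefficients for {zeros}")
        if self.reversible and not self.lower_bound < 0:
            raise IntegrityError(
                f"reaction {self.id}: reversible but lower bound {self.lower_bound} >= 0"
            )


@dataclass
class MetabolicModel:
    id: str
    compartments: Set[str] = field(default_factory=set)
    genes: Dict[str, Gene] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective: Optional[str] = None
    namespace: str = "default"
    boundary_compartment: str = "e"
    exchange_prefix: str = EXCHANGE_PREFIX

    # -- construction helpers -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise IntegrityError(f"duplicate metabolite id {met.id}")
        self.compartments.add(met.compartment)
        self.metabolites[met.id] = met
        return met

    def add_gene(self, gene: Gene) -> Gene:
        clashes = {g.lower() for g in self.genes}
        if gene.locus_tag.lower() in clashes:
            raise IntegrityError(f"duplicate locus tag {gene.locus_tag} (case-insensitive)")
        self.genes[gene.locus_tag] = gene
        return gene

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {rxn.id}")
        rxn.validate()
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise IntegrityError(f"reaction {rxn.id}: unknown metabolites {missing}")
        if rxn.gpr is not None:
            missing_genes = sorted(rxn.gpr.genes() - set(self.genes))
            if missing_genes:
                raise IntegrityError(
                    f"reaction {rxn.id}: GPR cites undeclared genes {missing_genes}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def validate(self) -> List[str]:
        """Return a list of integrity violations (empty when sound)."""
        problems: List[str] = []
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                problems.append(f"metabolite {met.id}: unknown compartment {met.compartment}")
        declared = set(self.genes)
        for rxn in self.reactions.values():
            try:
                rxn.validate()
            except IntegrityError as exc:
                problems.append(str(exc))
            for m in rxn.stoichiometry:
                if m not in self.metabolites:
                    problems.append(f"reaction {rxn.id}: unknown metabolite {m}")
            if rxn.gpr is not None:
                for g in sorted(rxn.gpr.genes() - declared):
                    problems.append(f"reaction {rxn.id}: GPR cites undeclared gene {g}")
        if self.objective is not None and self.objective not in self.reactions:
            problems.append(f"objective {self.objective} is not a reaction in the model")
        return problems

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- classification -------------------------------------------------------
    def classify_reaction(self, rxn: Reaction) -> ReactionKind:
        """Assign a reaction its structural kind.

        exchange: single metabolite in the boundary compartment, or the id
        carries the exchange prefix; demand: single non-boundary metabolite,
        irreversible; sink: single non-boundary metabolite, reversible;
        transport: spans >= 2 compartments with some base metabolite present
        in different compartments on opposite sides; otherwise internal.
        """
        mets = [self.metabolites[m] for m in rxn.stoichiometry]
        if len(mets) == 1:
            met = mets[0]
            if met.compartment == self.boundary_compartment or rxn.id.startswith(
                self.exchange_prefix
            ):
                return ReactionKind.EXCHANGE
            return ReactionKind.SINK if rxn.reversible else ReactionKind.DEMAND
        comps = {m.compartment for m in mets}
        if len(comps) >= 2:
            sub = {(self.metabolites[m].base_id(), self.metabolites[m].compartment)
                   for m in rxn.substrates()}
            prod = {(self.metabolites[m].base_id(), self.metabolites[m].compartment)
                    for m in rxn.products()}
            sub_bases = {b for b, _ in sub}
            for base, comp in prod:
                if base in sub_bases and (base, comp) not in sub:
                    return ReactionKind.TRANSPORT
        return ReactionKind.INTERNAL

    def reaction_kinds(self) -> Dict[str, ReactionKind]:
        return {rid: self.classify_reaction(r) for rid, r in self.reactions.items()}

    def internal_reactions(self) -> Dict[str, Reaction]:
        """Reactions that survive the boundary filter used by benchmarking."""
        return {
            rid: r
            for rid, r in self.reactions.items()
            if self.classify_reaction(r) == ReactionKind.INTERNAL
        }


def classify_reaction(rxn: Reaction, model: MetabolicModel) -> ReactionKind:
    """Functional alias for :meth:`MetabolicModel.classify_reaction`."""
    return model.classify_reaction(rxn)


def models_equal(a: MetabolicModel, b: MetabolicModel, atol: float = 0.0) -> bool:
    """Structural equality: compartments, gene/metabolite/reaction ids,
    stoichiometry, bounds, reversibility and GPR trees (order-insensitive)."""
    if a.compartments != b.compartments:
        return False
    if set(a.genes) != set(b.genes):
        return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        if (ma.compartment, ma.formula, ma.charge) != (mb.compartment, mb.formula, mb.charge):
            return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        for m, c in ra.stoichiometry.items():
            if abs(c - rb.stoichiometry[m]) > atol:
                return False
        if (ra.reversible, ra.lower_bound, ra.upper_bound) != (
            rb.reversible, rb.lower_bound, rb.upper_bound
        ):
            return False
        if not gpr_equal(ra.gpr, rb.gpr):
            return False
    return True


# -- universal reaction catalogue ---------------------------------------------

@dataclass
class CatalogueEntry:
    id: str
    name: str
    stoichiometry: Dict[str, float]  # compartment-free metabolite ids
    reversible: bool
    ec_numbers: Set[str]
    pathway: Optional[str] = None
    spontaneous: bool = False


@dataclass
class ReactionCatalogue:
    """EC -> reaction lookup standing in for a universal reaction database."""

    entries: Dict[str, CatalogueEntry] = field(default_factory=dict)

    def add(self, entry: CatalogueEntry) -> None:
        if entry.id in self.entries:
            raise IntegrityError(f"duplicate catalogue entry {entry.id}")
        if not entry.ec_numbers and not entry.spontaneous:
            raise IntegrityError(f"catalogue entry {entry.id} has no EC and is not spontaneous")
        self.entries[entry.id] = entry

    def by_ec(self) -> Dict[str, Set[str]]:
        index: Dict[str, Set[str]] = {}
        for entry in self.entries.values():
            for ec in entry.ec_numbers:
                index.setdefault(ec, set()).add(entry.id)
        return index

    @classmethod
    def read_tsv(cls, path) -> "ReactionCatalogue":
        """Read the documented catalogue TSV.

        Columns: id, name, equation, reversible (0/1), ec (;-separated),
        pathway, spontaneous (0/1).  Equation syntax:
        ``a + 2 b -> c`` or ``a <=> b`` with compartment-free species ids.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"id", "name", "equation", "reversible", "ec", "pathway", "spontaneous"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalogue file missing columns: {sorted(missing)}")
        cat = cls()
        for _, row in df.iterrows():
            stoich, reversible = parse_equation(row["equation"])
            cat.add(
                CatalogueEntry(
                    id=row["id"],
                    name=row["name"],
                    stoichiometry=stoich,
                    reversible=bool(int(row["reversible"])) or reversible,
                    ec_numbers={e for e in row["ec"].split(";") if e},
                    pathway=row["pathway"] or None,
                    spontaneous=bool(int(row["spontaneous"] or 0)),
                )
            )
        return cat

    def write_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for entry in sorted(self.entries.values(), key=lambda e: e.id):
            rows.append(
                {
                    "id": entry.id,
                    "name": entry.name,
                    "equation": format_equation(entry.stoichiometry, entry.reversible),
                    "reversible": int(entry.reversible),
                    "ec": ";".join(sorted(entry.ec_numbers)),
                    "pathway": entry.pathway or "",
                    "spontaneous": int(entry.spontaneous),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_equation(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 a + b -> c"`` / ``"a <=> b"`` into (stoichiometry, reversible)."""
    for arrow, reversible in (("<=>", True), ("<->", True), ("->", False), ("=>", False)):
        if arrow in text:
            lhs, rhs = text.split(arrow, 1)
            break
    else:
        raise ValueError(f"no reaction arrow in equation {text!r}")

    def side(chunk: str, sign: float, into: Dict[str, float]) -> None:
        chunk = chunk.strip()
        if not chunk:
            return
        for term in chunk.split(" + "):
            parts = term.strip().split()
            if not parts:
                continue
            if len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, met = 1.0, parts[0]
            else:
                raise ValueError(f"cannot parse equation term {term!r}")
            into[met] = into.get(met, 0.0) + sign * coeff

    stoich: Dict[str, float] = {}
    side(lhs, -1.0, stoich)
    side(rhs, +1.0, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return stoich, reversible


def format_equation(stoich: Dict[str, float], reversible: bool) -> str:
    def side(items):
        terms = []
        for met, coeff in sorted(items):
            terms.append(met if coeff == 1 else f"{coeff:g} {met}")
        return " + ".join(terms)

    lhs = side((m, -c) for m, c in stoich.items() if c < 0)
    rhs = side((m, c) for m, c in stoich.items() if c > 0)
    arrow = "<=>" if reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


def rehome_metabolite_id(met_id: str, compartment: str,
                         suffix_re: re.Pattern = COMPARTMENT_SUFFIX_RE) -> str:
    m = suffix_re.match(met_id)
    base = m.group("base") if m else met_id
    return f"{base}_{compartment}"


__all__ = [
    "Metabolite", "Gene", "Reaction", "MetabolicModel", "ReactionKind",
    "ReactionCatalogue", "CatalogueEntry", "IntegrityError", "classify_reaction",
    "models_equal", "parse_equation", "format_equation", "BOUNDARY_KINDS",
    "rehome_metabolite_id", "PSEUDO_PREFIX",
]
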