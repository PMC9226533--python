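"""Model refinement: compartment integration and network audits.

The audits are deliberately topological (no linear programming): a
reaction is flagged blocked when, by iterated dead-end propagation, one
of its substrates can never be made or one of its products can never be
consumed in any admissible direction.  This is sound (every flagged
reaction truly cannot carry steady-state flux) but incomplete compared
with an FVA-style solver check.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    rehome_metabolite_id,
)

logger = logging.getLogger(__name__)


# -- subcellular localization reports -----------------------------------------

class LocalizationParseError(ValueError):
    pass


@dataclass
class LocalizationReport:
    """Per-gene compartment predictions, scores normalised to [0, 1]."""

    predictions: Dict[str, List[Tuple[str, float]]] = field(default_factory=dict)
    dialect: str = "generic_tsv"

    def top(self, locus_tag: str) -> Optional[Tuple[str, float]]:
        preds = self.predictions.get(locus_tag)
        if not preds:
            return None
        return max(preds, key=lambda p: (p[1], p[0]))


def parse_localization_report(path, dialect: str) -> LocalizationReport:
    """Parse a localization prediction report.

    Dialects: ``psortb_long`` (0-10 scores), ``wolfpsort`` (k-NN votes,
    normalised by the per-gene vote total), ``loctree3`` (0-100 scores)
    and ``generic_tsv`` (three columns, scores already in [0, 1]).
    """
    parsers = {
        "psortb_long": _parse_psortb_long,
        "wolfpsort": _parse_wolfpsort,
        "loctree3": _parse_loctree3,
        "generic_tsv": _parse_generic_tsv,
    }
    if dialect not in parsers:
        raise ValueError(f"unknown localization dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    predictions = parsers[dialect](lines, str(path))
    return LocalizationReport(predictions=predictions, dialect=dialect)


def _slug(label: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", label.strip().lower()).strip("_")


def _parse_psortb_long(lines, path):
    predictions: Dict[str, List[Tuple[str, float]]] = {}
    current: Optional[str] = None
    in_scores = False
    for no, line in enumerate(lines, 1):
        if line.startswith("SeqID:"):
            current = line.split("SeqID:", 1)[1].strip().split()[0]
            predictions[current] = []
            in_scores = False
        elif "Localization Scores:" in line:
            if current is None:
                raise LocalizationParseError(f"{path}: line {no}: scores before any SeqID")
            in_scores = True
        elif in_scores:
            stripped = line.strip()
            if not stripped or stripped.startswith("Final Prediction"):
                in_scores = False
                continue
            parts = stripped.rsplit(None, 1)
            if len(parts) != 2:
                raise LocalizationParseError(f"{path}: line {no}: cannot parse {line!r}")
            label, score = parts
            try:
                value = float(score)
            except ValueError as exc:
                raise LocalizationParseError(f"{path}: line {no}: {exc}") from None
            if not 0 <= value <= 10:
                raise LocalizationParseError(
                    f"{path}: line {no}: score {value} outside the 0-10 scale"
                )
            predictions[current].append((_slug(label), value / 10.0))
    if current is None:
        raise LocalizationParseError(f"{path}: no SeqID records found")
    return predictions


def _parse_wolfpsort(lines, path):
    predictions: Dict[str, List[Tuple[str, float]]] = {}
    for no, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            gene, rest = line.split(None, 1)
            votes = []
            for chunk in rest.split(","):
                label, count = chunk.strip().rsplit(None, 1)
                votes.append((_slug(label), float(count)))
        except ValueError:
            raise LocalizationParseError(
                f"{path}: line {no}: cannot parse wolfpsort row {line!r}"
            ) from None
        if any(v < 0 for _, v in votes):
            raise LocalizationParseError(f"{path}: line {no}: negative vote count")
        total = sum(v for _, v in votes)
        if total <= 0:
            raise LocalizationParseError(f"{path}: line {no}: zero total votes")
        predictions[gene] = [(label, v / total) for label, v in votes]
    if not predictions:
        raise LocalizationParseError(f"{path}: no prediction rows found")
    return predictions


def _parse_loctree3(lines, path):
    predictions: Dict[str, List[Tuple[str, float]]] = {}
    for no, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise LocalizationParseError(
                f"{path}: line {no}: expected id<TAB>score<TAB>localization"
            )
        gene, score, label = parts[0], parts[1], parts[2]
        try:
            value = float(score)
        except ValueError as exc:
            raise LocalizationParseError(f"{path}: line {no}: {exc}") from None
        if not 0 <= value <= 100:
            raise LocalizationParseError(
                f"{path}: line {no}: score {value} outside the 0-100 scale"
            )
        predictions.setdefault(gene, []).append((_slug(label), value / 100.0))
    if not predictions:
        raise LocalizationParseError(f"{path}: no prediction rows found")
    return predictions


def _parse_generic_tsv(lines, path):
    predictions: Dict[str, List[Tuple[str, float]]] = {}
    for no, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LocalizationParseError(
                f"{path}: line {no}: expected locus_tag<TAB>compartment<TAB>score"
            )
        gene, label, score = parts
        try:
            value = float(score)
        except ValueError as exc:
            raise LocalizationParseError(f"{path}: line {no}: {exc}") from None
        if not 0 <= value <= 1:
            raise LocalizationParseError(f"{path}: line {no}: score {value} outside [0, 1]")
        predictions.setdefault(gene, []).append((_slug(label), value))
    if not predictions:
        raise LocalizationParseError(f"{path}: no prediction rows found")
    return predictions


# -- compartment integration --------------------------------------------------

def integrate_compartments(
    model: MetabolicModel,
    report: LocalizationReport,
    threshold: float = 0.5,
    default_compartment: str = "c",
) -> MetabolicModel:
    """Re-home reactions by their genes' predicted compartments.

    A gene adopts its top-scoring compartment when that score clears the
    threshold, else the default.  Each GPR-bearing reaction moves to the
    majority compartment of its genes (ties and unknown genes fall back
    to the default); its non-boundary metabolites are re-suffixed.
    Idempotent at fixed inputs.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    out = model.copy()
    if default_compartment not in out.compartments:
        raise ValueError(f"default compartment {default_compartment!r} not in model")

    gene_comp: Dict[str, str] = {}
    for tag in out.genes:
        top = report.top(tag)
        if top is not None and top[1] >= threshold:
            gene_comp[tag] = top[0]
        else:
            gene_comp[tag] = default_compartment

    for rxn in out.reactions.values():
        if rxn.gpr is None:
            continue
        votes = Counter(gene_comp.get(g, default_compartment) for g in sorted(rxn.gpr.genes()))
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            home = default_compartment
        else:
            home = ranked[0][0]
        out.compartments.add(home)
        renamed: Dict[str, float] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            met = out.metabolites[met_id]
            if met.pseudo or met.compartment == out.boundary_compartment:
                new_id = met_id
            else:
                new_id = rehome_metabolite_id(met_id, home)
                if new_id not in out.metabolites:
                    out.add_metabolite(Metabolite(
                        id=new_id, name=met.name, compartment=home,
                        formula=met.formula, charge=met.charge,
                    ))
            renamed[new_id] = renamed.get(new_id, 0.0) + coeff
        renamed = {m: c for m, c in renamed.items() if c != 0}
        if renamed:
            rxn.stoichiometry = renamed

    # prune metabolites no longer referenced by any reaction
    used = {m for r in out.reactions.values() for m in r.stoichiometry}
    out.metabolites = {mid: met for mid, met in out.metabolites.items() if mid in used}
    return out


# -- elemental balance --------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Hill-notation formula -> element counts (no parentheses support)."""
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"unparsable formula token at {formula[pos:]!r}")
        element, digits = m.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


@dataclass
class BalanceIssue:
    reaction_id: str
    status: str  # "unbalanced" | "unknown"
    element_imbalance: Dict[str, float] = field(default_factory=dict)
    charge_imbalance: Optional[float] = None
    detail: str = ""


def check_mass_balance(model: MetabolicModel, tol: float = 1e-9) -> List[BalanceIssue]:
    """Flag elementally (and charge-) unbalanced internal reactions.

    Pseudo-species and exchange/sink/demand reactions are skipped.  A
    reaction citing a metabolite without a formula is reported with
    status "unknown".  Imbalances are the signed products-minus-
    substrates element sums.
    """
    issues: List[BalanceIssue] = []
    kinds = model.reaction_kinds()
    for rxn_id in sorted(model.reactions):
        rxn = model.reactions[rxn_id]
        if kinds[rxn_id] in (ReactionKind.EXCHANGE, ReactionKind.SINK, ReactionKind.DEMAND):
            continue
        balance: Dict[str, float] = {}
        charge = 0.0
        charge_known = True
        unknown_reason = None
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.pseudo:
                continue
            if met.formula is None:
                unknown_reason = f"metabolite {met_id} has no formula"
                break
            try:
                counts = parse_formula(met.formula)
            except ValueError as exc:
                unknown_reason = f"metabolite {met_id}: {exc}"
                break
            for element, count in counts.items():
                balance[element] = balance.get(element, 0.0) + coeff * count
            if met.charge is None:
                charge_known = False
            else:
                charge += coeff * met.charge
        if unknown_reason is not None:
            issues.append(BalanceIssue(rxn_id, "unknown", detail=unknown_reason))
            continue
        imbalance = {e: v for e, v in balance.items() if abs(v) > tol}
        charge_imb = charge if charge_known and abs(charge) > tol else None
        if imbalance or charge_imb is not None:
            issues.append(BalanceIssue(rxn_id, "unbalanced", imbalance, charge_imb))
    return issues


# -- dead ends and blocked reactions ------------------------------------------

def _directions(model: MetabolicModel, rxn: Reaction, kind: ReactionKind) -> Set[str]:
    dirs: Set[str] = set()
    if kind == ReactionKind.EXCHANGE:
        return {"+", "-"}  # boundary species may always enter or leave
    if rxn.upper_bound > 0:
        dirs.add("+")
    if rxn.lower_bound < 0:
        dirs.add("-")
    return dirs


def _produced(rxn: Reaction, direction: str) -> Set[str]:
    return set(rxn.products() if direction == "+" else rxn.substrates())


def _consumed(rxn: Reaction, direction: str) -> Set[str]:
    return set(rxn.substrates() if direction == "+" else rxn.products())


def find_dead_ends(model: MetabolicModel) -> Tuple[Set[str], Set[str]]:
    """(never_produced, never_consumed) metabolite id sets.

    Reversible reactions count both ways; exchanges count as both
    producers and consumers of their species.
    """
    kinds = model.reaction_kinds()
    producible: Set[str] = set()
    consumable: Set[str] = set()
    for rxn_id, rxn in model.reactions.items():
        for direction in _directions(model, rxn, kinds[rxn_id]):
            producible |= _produced(rxn, direction)
            consumable |= _consumed(rxn, direction)
    mets = set(model.metabolites)
    return mets - producible, mets - consumable


def find_blocked_reactions(model: MetabolicModel) -> Set[str]:
    """Reactions that provably cannot carry steady-state flux.

    Iterates to a fixpoint: a direction is dropped when one of its
    substrates is producible by no remaining direction or one of its
    products is consumable by none; a reaction is blocked when all its
    directions are dropped.
    """
    kinds = model.reaction_kinds()
    active: Dict[str, Set[str]] = {
        rxn_id: _directions(model, rxn, kinds[rxn_id])
        for rxn_id, rxn in model.reactions.items()
    }
    changed = True
    while changed:
        changed = False
        producible: Set[str] = set()
        consumable: Set[str] = set()
        for rxn_id, dirs in active.items():
            rxn = model.reactions[rxn_id]
            for direction in dirs:
                producible |= _produced(rxn, direction)
                consumable |= _consumed(rxn, direction)
        for rxn_id, dirs in active.items():
            rxn = model.reactions[rxn_id]
            keep = {
                d for d in dirs
                if _consumed(rxn, d) <= producible and _produced(rxn, d) <= consumable
            }
            if keep != dirs:
                active[rxn_id] = keep
                changed = True
    return {rxn_id for rxn_id, dirs in active.items() if not dirs}


__all__ = [
    "LocalizationReport", "LocalizationParseError", "parse_localization_report",
    "integrate_compartments", "BalanceIssue", "check_mass_balance", "parse_formula",
    "find_dead_ends", "find_blocked_reactions",
]
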