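"""Enzyme annotation from homology-search results.

Each gene's alignment hits vote for EC numbers and product names.  A
label's score blends how often it occurs among the hits (frequency) with
how taxonomically close its best supporting subject is to the target
organism (shared-lineage prefix similarity):

    score = alpha * frequency + (1 - alpha) * taxonomy_score

Labels at or above the threshold ``tau`` are committed.  As an
alternative to scoring, :func:`automatic_workflow` adopts annotations
from an ordered priority list of taxa, preferring hits from organisms
the user trusts most.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

DEFAULT_ALPHA = 0.5
DEFAULT_TAU = 0.5

#: mandatory columns of the extended tabular alignment format
ALIGNMENT_COLUMNS = [
    "query", "subject", "identity", "alignment_length", "mismatches", "gap_opens",
    "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
    "subject_organism", "subject_lineage", "subject_ec", "subject_product",
]
OPTIONAL_COLUMNS = ["reviewed"]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    bitscore: float
    evalue: float
    identity: float
    subject_organism: str
    subject_lineage: Tuple[str, ...]
    subject_ec: frozenset = frozenset()
    subject_product: str = ""
    reviewed: bool = False

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"hit {self.query}->{self.subject}: negative e-value")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"hit {self.query}->{self.subject}: identity outside [0, 100]")
        if not self.subject_lineage:
            raise ValueError(f"hit {self.query}->{self.subject}: empty lineage")


@dataclass(frozen=True)
class AnnotationCandidate:
    label: str
    frequency: float
    taxonomy_score: float
    score: float
    supporting_hits: int
    kind: str = "ec"  # "ec" or "product"


class AnnotationStatus(str, Enum):
    ANNOTATED = "annotated"
    BELOW_THRESHOLD = "below_threshold"
    NO_HITS = "no_hits"
    MANUAL = "manual"


@dataclass
class GeneAnnotation:
    locus_tag: str
    product: Optional[str] = None
    ec_numbers: Set[str] = field(default_factory=set)
    score: float = 0.0
    status: AnnotationStatus = AnnotationStatus.NO_HITS
    fallback: bool = False  # automatic workflow matched no priority taxon


@dataclass
class AnnotationTable:
    entries: Dict[str, GeneAnnotation] = field(default_factory=dict)

    def set(self, ann: GeneAnnotation) -> None:
        existing = self.entries.get(ann.locus_tag)
        if existing is not None and existing.status == AnnotationStatus.MANUAL:
            return  # manual curation is never overwritten by re-runs
        self.entries[ann.locus_tag] = ann

    def set_manual(self, locus_tag: str, product: Optional[str], ecs: Iterable[str]) -> None:
        self.entries[locus_tag] = GeneAnnotation(
            locus_tag=locus_tag, product=product, ec_numbers=set(ecs),
            score=1.0, status=AnnotationStatus.MANUAL,
        )

    def annotated_ecs(self) -> Dict[str, Set[str]]:
        """locus tag -> committed EC set, for annotated/manual genes only."""
        return {
            tag: set(a.ec_numbers)
            for tag, a in self.entries.items()
            if a.status in (AnnotationStatus.ANNOTATED, AnnotationStatus.MANUAL)
            and a.ec_numbers
        }

    def write_tsv(self, path) -> None:
        rows = [
            {
                "locus_tag": a.locus_tag,
                "product": a.product or "",
                "ec": ";".join(sorted(a.ec_numbers)),
                "score": f"{a.score:.6f}",
                "status": a.status.value,
                "fallback": int(a.fallback),
            }
            for a in sorted(self.entries.values(), key=lambda a: a.locus_tag)
        ]
        pd.DataFrame(
            rows, columns=["locus_tag", "product", "ec", "score", "status", "fallback"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        table = cls()
        for _, row in df.iterrows():
            table.entries[row["locus_tag"]] = GeneAnnotation(
                locus_tag=row["locus_tag"],
                product=row["product"] or None,
                ec_numbers={e for e in row["ec"].split(";") if e},
                score=float(row["score"] or 0.0),
                status=AnnotationStatus(row["status"]),
                fallback=bool(int(row["fallback"] or 0)),
            )
        return table


# -- loading ------------------------------------------------------------------

def load_alignment_table(path, dialect: str = "extended") -> Dict[str, List[AlignmentHit]]:
    """Load the extended 16-column alignment TSV, grouped by query.

    Hits within a group are sorted by descending bitscore.  Rows with
    unparsable numeric fields are rejected with their line numbers.
    """
    if dialect != "extended":
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
    hits: Dict[str, List[AlignmentHit]] = {}
    bad_lines: List[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            hit = AlignmentHit(
                query=row["query"],
                subject=row["subject"],
                bitscore=float(row["bitscore"]),
                evalue=float(row["evalue"]),
                identity=float(row["identity"]),
                subject_organism=row["subject_organism"],
                subject_lineage=tuple(
                    r for r in str(row["subject_lineage"]).split(";") if r
                ),
                subject_ec=frozenset(
                    e for e in str(row["subject_ec"] or "").split(";")
                    if e and e != "nan"
                ),
                subject_product=str(row["subject_product"] or ""),
                reviewed=str(row.get("reviewed", "0")) in ("1", "True", "true"),
            )
        except (ValueError, TypeError) as exc:
            bad_lines.append(f"line {line_no}: {exc}")
            continue
        hits.setdefault(hit.query, []).append(hit)
    if bad_lines:
        raise SchemaError(f"{path}: rejected rows:\n  " + "\n  ".join(bad_lines))
    for query in hits:
        hits[query].sort(key=lambda h: (-h.bitscore, h.evalue, h.subject))
    return hits


# -- scoring ------------------------------------------------------------------

def lineage_similarity(subject: Sequence[str], target: Sequence[str]) -> float:
    """Shared leading-rank count over the longer lineage length."""
    shared = 0
    for a, b in zip(subject, target):
        if a.strip().lower() != b.strip().lower():
            break
        shared += 1
    return shared / max(len(subject), len(target))


def normalize_product(product: str) -> str:
    return re.sub(r"\s+", " ", product.strip()).lower()


def score_candidates(
    hits_for_gene: Sequence[AlignmentHit],
    target_lineage: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    kind: str = "ec",
) -> List[AnnotationCandidate]:
    """Score each distinct EC (or normalised product) among a gene's hits.

    frequency(label) is the fraction of hits carrying the label;
    taxonomy_score(label) is the best lineage similarity among its
    supporting hits.  Candidates are sorted by score, then frequency,
    then label (all descending except the lexicographic label).
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if not hits_for_gene:
        return []
    queries = {h.query for h in hits_for_gene}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")

    supporters: Dict[str, List[AlignmentHit]] = {}
    for hit in hits_for_gene:
        if kind == "ec":
            labels = hit.subject_ec
        else:
            labels = {normalize_product(hit.subject_product)} if hit.subject_product else set()
        for label in labels:
            supporters.setdefault(label, []).append(hit)

    n = len(hits_for_gene)
    candidates = []
    for label, label_hits in supporters.items():
        freq = len(label_hits) / n
        tax = max(lineage_similarity(h.subject_lineage, target_lineage) for h in label_hits)
        candidates.append(
            AnnotationCandidate(
                label=label,
                frequency=freq,
                taxonomy_score=tax,
                score=alpha * freq + (1 - alpha) * tax,
                supporting_hits=len(label_hits),
                kind=kind,
            )
        )
    candidates.sort(key=lambda c: (-c.score, -c.frequency, c.label))
    return candidates


def select_annotation(
    candidates: Sequence[AnnotationCandidate], tau: float = DEFAULT_TAU
) -> Tuple[Optional[str], float, AnnotationStatus]:
    """Commit the top candidate when its score clears the threshold."""
    if not candidates:
        return None, 0.0, AnnotationStatus.NO_HITS
    top = candidates[0]
    if top.score >= tau:
        return top.label, top.score, AnnotationStatus.ANNOTATED
    return None, top.score, AnnotationStatus.BELOW_THRESHOLD


def annotate_genome(
    hits: Dict[str, List[AlignmentHit]],
    target_lineage: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    tau: float = DEFAULT_TAU,
    table: Optional[AnnotationTable] = None,
) -> AnnotationTable:
    """Score-and-threshold annotation of every gene with hits."""
    table = table or AnnotationTable()
    for locus_tag in sorted(hits):
        gene_hits = hits[locus_tag]
        ec_cands = score_candidates(gene_hits, target_lineage, alpha, kind="ec")
        prod_cands = score_candidates(gene_hits, target_lineage, alpha, kind="product")
        ec_label, ec_score, ec_status = select_annotation(ec_cands, tau)
        prod_label, _, _ = select_annotation(prod_cands, tau)
        table.set(
            GeneAnnotation(
                locus_tag=locus_tag,
                product=prod_label,
                ec_numbers={ec_label} if ec_label else set(),
                score=ec_score,
                status=ec_status,
            )
        )
    return table


# -- taxonomy-priority automatic workflow -------------------------------------

def _matches_taxon(hit: AlignmentHit, taxon: str) -> bool:
    taxon = taxon.lower()
    if taxon in hit.subject_organism.lower():
        return True
    return any(taxon == rank.strip().lower() for rank in hit.subject_lineage)


def automatic_workflow(
    hits: Dict[str, List[AlignmentHit]],
    priority_taxa: Sequence[str],
    table: Optional[AnnotationTable] = None,
) -> AnnotationTable:
    """Adopt product/EC from the hit of the most trusted taxon.

    Hits are ranked by (index of the first priority taxon they match,
    then descending bitscore, then subject accession); genes whose hits
    match no listed taxon fall back to the best-bitscore hit and are
    flagged.
    """
    if not priority_taxa:
        raise ValueError("priority_taxa must be non-empty")
    table = table or AnnotationTable()
    for locus_tag in sorted(hits):
        gene_hits = hits[locus_tag]
        if not gene_hits:
            table.set(GeneAnnotation(locus_tag=locus_tag))
            continue

        def priority_index(hit: AlignmentHit) -> int:
            for i, taxon in enumerate(priority_taxa):
                if _matches_taxon(hit, taxon):
                    return i
            return len(priority_taxa)

        ranked = sorted(gene_hits, key=lambda h: (priority_index(h), -h.bitscore, h.subject))
        best = ranked[0]
        fallback = priority_index(best) == len(priority_taxa)
        table.set(
            GeneAnnotation(
                locus_tag=locus_tag,
                product=best.subject_product or None,
                ec_numbers=set(best.subject_ec),
                score=1.0 if not fallback else 0.0,
                status=AnnotationStatus.ANNOTATED,
                fallback=fallback,
            )
        )
    return table


# -- parameter search ---------------------------------------------------------

def grid_search_parameters(
    hits: Dict[str, List[AlignmentHit]],
    target_lineage: Sequence[str],
    labelled_sample: Dict[str, Set[str]],
    alphas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    taus: Sequence[float] = (0.25, 0.5, 0.75),
) -> Tuple[float, float, float]:
    """Pick (alpha, tau) maximising EC-annotation F1 on a labelled sample.

    ``labelled_sample`` maps locus tags to their manually assigned EC
    sets (empty set = the curator says "no enzyme").  Returns
    (best_alpha, best_tau, best_f1); ties prefer smaller alpha then
    smaller tau for determinism.
    """
    best = (0.0, 0.0, -1.0)
    for alpha in alphas:
        for tau in taus:
            tp = fp = fn = 0
            for tag, truth in labelled_sample.items():
                cands = score_candidates(hits.get(tag, []), target_lineage, alpha, kind="ec")
                label, _, status = select_annotation(cands, tau)
                predicted = {label} if status == AnnotationStatus.ANNOTATED else set()
                tp += len(predicted & truth)
                fp += len(predicted - truth)
                fn += len(truth - predicted)
            f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            if f1 > best[2]:
                best = (alpha, tau, f1)
    return best


__all__ = [
    "AlignmentHit", "AnnotationCandidate", "AnnotationStatus", "GeneAnnotation",
    "AnnotationTable", "load_alignment_table", "score_candidates",
    "select_annotation", "annotate_genome", "automatic_workflow",
    "grid_search_parameters", "lineage_similarity", "normalize_product",
    "SchemaError", "ALIGNMENT_COLUMNS", "DEFAULT_ALPHA", "DEFAULT_TAU",
]
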