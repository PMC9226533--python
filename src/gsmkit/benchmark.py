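"""Draft-versus-curated model comparison.

Reaction identifiers are translated between database namespaces through
a hub-keyed cross-reference (alias) table before counting.  Transport,
exchange, sink and demand reactions are excluded from both sides: their
identifier conversion is not reliable across namespaces.  Gene sets are
compared by case-insensitive locus tag.  Five metrics summarise each
comparison: precision, recall, TP/FP ratio, F1 and Jaccard distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .model import MetabolicModel


@dataclass
class AliasTable:
    """Many-to-many (namespace, external id) <-> hub id cross-reference.

    Namespace comparison is case-insensitive; ids are case-preserving.
    An :meth:`identity` table maps every id to itself in any namespace
    (useful for self-comparisons and planted-truth tests).
    """

    records: List[Tuple[str, str, str]] = field(default_factory=list)
    identity_mode: bool = False
    _to_hub: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict, repr=False)
    _from_hub: Dict[str, Dict[str, Set[str]]] = field(default_factory=dict, repr=False)

    def add(self, namespace: str, external_id: str, hub_id: str) -> None:
        namespace = namespace.lower()
        self.records.append((namespace, external_id, hub_id))
        self._to_hub.setdefault((namespace, external_id), set()).add(hub_id)
        self._from_hub.setdefault(hub_id, {}).setdefault(namespace, set()).add(external_id)

    @classmethod
    def identity(cls) -> "AliasTable":
        return cls(identity_mode=True)

    @classmethod
    def read_tsv(cls, path) -> "AliasTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"namespace", "external_id", "hub_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: alias table missing columns {sorted(missing)}")
        table = cls()
        for _, row in df.iterrows():
            table.add(row["namespace"], row["external_id"], row["hub_id"])
        return table

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.records), columns=["namespace", "external_id", "hub_id"]
        ).to_csv(path, sep="\t", index=False)

    def hubs(self, namespace: str, external_id: str) -> Set[str]:
        if self.identity_mode:
            return {external_id}
        return set(self._to_hub.get((namespace.lower(), external_id), set()))

    def translate(self, namespace: str, external_id: str, target_namespace: str) -> Set[str]:
        """External id -> union over its hubs of the target-namespace ids."""
        if self.identity_mode:
            return {external_id}
        out: Set[str] = set()
        for hub in self.hubs(namespace, external_id):
            out |= self._from_hub.get(hub, {}).get(target_namespace.lower(), set())
        return out

    def known_namespaces(self) -> Set[str]:
        return {ns for ns, _, _ in self.records}


@dataclass
class ConversionStats:
    total: int
    converted: int

    @property
    def unconverted(self) -> int:
        return self.total - self.converted


def convert_reaction_ids(
    model: MetabolicModel,
    aliases: AliasTable,
    target_namespace: str,
    reaction_ids: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, Set[str]], ConversionStats]:
    """Map each reaction id into the target namespace via the hub table."""
    if not aliases.identity_mode and model.namespace.lower() not in aliases.known_namespaces():
        raise ValueError(
            f"model namespace {model.namespace!r} unknown to the alias table"
        )
    ids = list(reaction_ids) if reaction_ids is not None else sorted(model.reactions)
    mapping = {
        rid: aliases.translate(model.namespace, rid, target_namespace) for rid in ids
    }
    stats = ConversionStats(
        total=len(mapping), converted=sum(1 for v in mapping.values() if v)
    )
    return mapping, stats


@dataclass
class SetComparison:
    tp_items: Set[str] = field(default_factory=set)
    fp_items: Set[str] = field(default_factory=set)
    fn_items: Set[str] = field(default_factory=set)

    @property
    def tp(self) -> int:
        return len(self.tp_items)

    @property
    def fp(self) -> int:
        return len(self.fp_items)

    @property
    def fn(self) -> int:
        return len(self.fn_items)


@dataclass
class MetricSet:
    precision: float
    recall: float
    ratio: float  # TP/FP; +inf when FP == 0 and TP > 0
    f1: float
    jaccard_distance: float


def compute_metrics(cmp: SetComparison) -> MetricSet:
    """Precision, recall, TP/FP ratio, F1 and Jaccard distance.

    Degenerate conventions: precision 0 when TP+FP = 0; recall 0 when
    TP+FN = 0; F1 = 0 when P+R = 0; ratio is +inf when FP = 0 with
    TP > 0 and 0 when TP = 0; Jaccard distance 1 when all counts are 0.
    """
    tp, fp, fn = cmp.tp, cmp.fp, cmp.fn
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    if tp == 0:
        ratio = 0.0
    elif fp == 0:
        ratio = math.inf
    else:
        ratio = tp / fp
    union = tp + fp + fn
    jaccard_distance = 1.0 - (tp / union if union else 0.0)
    return MetricSet(precision, recall, ratio, f1, jaccard_distance)


def compare_reactions(
    draft: MetabolicModel, curated: MetabolicModel, aliases: AliasTable
) -> Tuple[SetComparison, ConversionStats]:
    """Alias-mediated reaction-set comparison after the boundary filter.

    Transport, exchange, sink and demand reactions are removed from both
    models first.  A draft reaction is a TP when its converted id set
    hits at least one curated internal reaction, an FP otherwise; FN are
    the curated internal reactions hit by no draft reaction.  A
    multi-alias draft reaction counts once however many curated ids it
    matches.
    """
    draft_internal = sorted(draft.internal_reactions())
    curated_internal = set(curated.internal_reactions())
    mapping, stats = convert_reaction_ids(
        draft, aliases, curated.namespace, reaction_ids=draft_internal
    )
    cmp = SetComparison()
    hit_curated: Set[str] = set()
    for rid in draft_internal:
        matched = mapping[rid] & curated_internal
        if matched:
            cmp.tp_items.add(rid)
            hit_curated |= matched
        else:
            cmp.fp_items.add(rid)
    cmp.fn_items = curated_internal - hit_curated
    return cmp, stats


def compare_genes(draft: MetabolicModel, curated: MetabolicModel) -> SetComparison:
    """Case-insensitive locus-tag set comparison."""
    draft_tags = {t.lower(): t for t in draft.genes}
    curated_tags = {t.lower(): t for t in curated.genes}
    shared = set(draft_tags) & set(curated_tags)
    return SetComparison(
        tp_items={draft_tags[t] for t in shared},
        fp_items={draft_tags[t] for t in set(draft_tags) - shared},
        fn_items={curated_tags[t] for t in set(curated_tags) - shared},
    )


def benchmark_report(
    drafts: Sequence[Tuple[str, MetabolicModel]],
    curated: MetabolicModel,
    aliases: AliasTable,
) -> pd.DataFrame:
    """One row per draft per entity type (reactions, genes), sorted by F1.

    Columns carry the TP/FP/FN counts, the five metrics and the id
    conversion statistics.
    """
    if not drafts:
        raise ValueError("at least one draft model is required")
    rows = []
    for name, draft in drafts:
        rxn_cmp, stats = compare_reactions(draft, curated, aliases)
        gene_cmp = compare_genes(draft, curated)
        for entity, cmp, conv in (
            ("reactions", rxn_cmp, stats),
            ("genes", gene_cmp, None),
        ):
            metrics = compute_metrics(cmp)
            rows.append({
                "draft": name,
                "entity": entity,
                "tp": cmp.tp, "fp": cmp.fp, "fn": cmp.fn,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "ratio": metrics.ratio,
                "f1": metrics.f1,
                "jaccard_distance": metrics.jaccard_distance,
                "converted": conv.converted if conv else pd.NA,
                "unconverted": conv.unconverted if conv else pd.NA,
            })
    df = pd.DataFrame(rows)
    df = (
        df.sort_values(["entity", "f1", "draft"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    return df


__all__ = [
    "AliasTable", "ConversionStats", "SetComparison", "MetricSet",
    "convert_reaction_ids", "compare_reactions", "compare_genes",
    "compute_metrics", "benchmark_report",
]
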