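"""Cross-family aggregation of retained variants in a two-stage design.

Families are screened independently; genes recur when retained variants hit
them in several families, identical variants shared by two families are
flagged, gene symbols sharing a prefix (e.g. the LRR superfamily) can be
grouped, and discovery-stage genes are reconciled against the validation
stage either exactly or at the gene-family level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError
from .io_formats import AnnotatedVariant, VariantKey

__all__ = [
    "DISCOVERY",
    "VALIDATION",
    "Stage",
    "FamilyCandidates",
    "GeneRecurrence",
    "StageReconciliation",
    "aggregate_by_gene",
    "group_gene_family",
    "reconcile_stages",
    "annotate_categories",
    "rank_candidates",
]

DISCOVERY = "discovery"
VALIDATION = "validation"
Stage = str


@dataclass
class FamilyCandidates:
    """Retained (post-filter) variants of one family at one stage."""

    family_id: str
    stage: Stage
    variants: list[AnnotatedVariant]


@dataclass
class GeneRecurrence:
    """Per-gene roll-up: which families and variants hit the gene.

    ``shared_identical_variants`` holds variant keys observed in at least two
    distinct families — the strongest form of recurrence.
    """

    gene: str
    families: set[str]
    variants: set[VariantKey]
    stages: set[Stage]
    shared_identical_variants: set[VariantKey] = field(default_factory=set)
    records: list[AnnotatedVariant] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def min_maf(self) -> float | None:
        """Smallest aggregate MAF over the gene's variants; None if all missing."""
        mafs = [r.aggregate_maf for r in self.records if r.aggregate_maf is not None]
        return min(mafs) if mafs else None


def aggregate_by_gene(candidates: Iterable[FamilyCandidates]) -> list[GeneRecurrence]:
    """Roll per-family retained variants up to one record per gene.

    Families are counted distinctly; a variant key seen in two or more
    families enters ``shared_identical_variants``.
    """
    by_gene: dict[str, GeneRecurrence] = {}
    carriers: dict[tuple[str, VariantKey], set[str]] = {}
    for fam in candidates:
        for variant in fam.variants:
            rec = by_gene.get(variant.gene)
            if rec is None:
                rec = by_gene[variant.gene] = GeneRecurrence(
                    gene=variant.gene, families=set(), variants=set(), stages=set()
                )
            rec.families.add(fam.family_id)
            rec.variants.add(variant.key)
            rec.stages.add(fam.stage)
            rec.records.append(variant)
            carriers.setdefault((variant.gene, variant.key), set()).add(fam.family_id)
    for (gene, key), fams in carriers.items():
        if len(fams) >= 2:
            by_gene[gene].shared_identical_variants.add(key)
    return [by_gene[g] for g in sorted(by_gene)]


def _compile_prefix(prefix_pattern: str) -> re.Pattern:
    try:
        return re.compile(f"^(?:{prefix_pattern})")
    except re.error as exc:
        raise ConfigurationError(f"invalid gene-family prefix pattern {prefix_pattern!r}: {exc}") from exc


def group_gene_family(
    recurrences: Iterable[GeneRecurrence],
    prefix_pattern: str,
) -> dict[str, set[str]]:
    """Group genes whose symbol matches an anchored prefix under one label.

    Non-matching genes stay under their own symbol.  The label of the
    matching group is the pattern itself (e.g. ``"LRR"``).
    """
    pattern = _compile_prefix(prefix_pattern)
    groups: dict[str, set[str]] = {}
    for rec in recurrences:
        label = prefix_pattern if pattern.match(rec.gene) else rec.gene
        groups.setdefault(label, set()).add(rec.gene)
    return groups


@dataclass
class StageReconciliation:
    """Discovery genes supported by the validation stage."""

    exact: set[str]                      # same gene in both stages
    group: dict[str, set[str]] = field(default_factory=dict)  # discovery gene -> validation genes in its family group

    @property
    def replicated(self) -> set[str]:
        return self.exact | set(self.group)


def reconcile_stages(
    discovery: Iterable[GeneRecurrence],
    validation: Iterable[GeneRecurrence],
    gene_family_pattern: str | None = None,
) -> StageReconciliation:
    """Find discovery genes replicated in validation families.

    Exact replication: the same gene symbol carries retained variants in both
    stages.  Group replication (when a prefix pattern is given): a discovery
    gene whose prefix-defined family contains at least one validation gene.
    """
    discovery_genes = {r.gene for r in discovery}
    validation_genes = {r.gene for r in validation}
    exact = discovery_genes & validation_genes

    group: dict[str, set[str]] = {}
    if gene_family_pattern is not None:
        pattern = _compile_prefix(gene_family_pattern)
        validation_in_group = {g for g in validation_genes if pattern.match(g)}
        if validation_in_group:
            for gene in discovery_genes - exact:
                if pattern.match(gene):
                    group[gene] = set(validation_in_group)
    return StageReconciliation(exact=exact, group=group)


def annotate_categories(
    recurrences: Sequence[GeneRecurrence],
    category_map: Mapping[str, Sequence[str] | str],
) -> pd.DataFrame:
    """Join user-supplied functional category labels onto the recurrence table.

    Genes absent from the map are labeled ``unclassified``.  Multi-label
    genes emit their labels in the given order, joined by ``;``.
    """
    rows = []
    for rec in recurrences:
        labels = category_map.get(rec.gene, ["unclassified"])
        if isinstance(labels, str):
            labels = [labels]
        rows.append(
            {
                "gene": rec.gene,
                "n_families": rec.n_families,
                "stages": ";".join(sorted(rec.stages)),
                "categories": ";".join(labels),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_families", "stages", "categories"])


def rank_candidates(recurrences: Iterable[GeneRecurrence]) -> list[GeneRecurrence]:
    """Deterministic candidate order.

    Family count descending, then minimum aggregate MAF ascending with
    missing MAF first (novelty ranks highest), then gene symbol.
    """
    def sort_key(rec: GeneRecurrence):
        maf = rec.min_maf
        return (-rec.n_families, maf is not None, maf if maf is not None else 0.0, rec.gene)

    return sorted(recurrences, key=sort_key)


def recurrence_table(recurrences: Sequence[GeneRecurrence]) -> pd.DataFrame:
    """Flat per-gene TSV-ready table of the aggregation product."""
    rows = []
    for rec in recurrences:
        rows.append(
            {
                "gene": rec.gene,
                "n_families": rec.n_families,
                "families": ";".join(sorted(rec.families)),
                "stages": ";".join(sorted(rec.stages)),
                "variants": ";".join(str(k) for k in sorted(rec.variants)),
                "shared_variants": ";".join(str(k) for k in sorted(rec.shared_identical_variants)),
                "min_maf": rec.min_maf if rec.min_maf is not None else "NA",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_families", "families", "stages", "variants", "shared_variants", "min_maf"],
    )
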