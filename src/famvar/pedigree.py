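"""Pedigree model and autosomal-dominant co-segregation filtering.

The first filtering stage of the pipeline: a variant is kept for a family
only if it travels with the disease phenotype under a fully-penetrant
autosomal-dominant model — affected members carry it (heterozygously, by
default) and unaffected members do not.  Tolerance knobs exist because real
pedigrees show incomplete penetrance and phenocopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .exceptions import ConsistencyError
from .io_formats import Call, GenotypeMatrix, VariantKey

__all__ = [
    "Sex",
    "Affection",
    "PedigreeMember",
    "Pedigree",
    "MissingGenotypeRule",
    "SegregationPolicy",
    "SegregationResult",
    "validate",
    "mendelian_consistent",
    "check_autosomal_dominant",
    "filter_segregating",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    sequenced: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A family: members keyed by individual id, with parent links."""

    family_id: str
    members: dict[str, PedigreeMember]

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.affection is Affection.AFFECTED]

    @property
    def unaffected(self) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.affection is Affection.UNAFFECTED]

    @property
    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.is_founder]


def validate(pedigree: Pedigree) -> list[str]:
    """Return human-readable issues; empty list iff the pedigree is well formed.

    Errors: dangling parent references, parent-graph cycles (reported with
    the offending id chain).  Warnings (prefixed "warning"): father coded
    female / mother coded male.
    """
    issues: list[str] = []
    members = pedigree.members
    for member in members.values():
        for role, parent_id in (("father", member.father_id), ("mother", member.mother_id)):
            if parent_id is None:
                continue
            parent = members.get(parent_id)
            if parent is None:
                issues.append(f"member {member.individual_id!r} references absent {role} {parent_id!r}")
            elif role == "father" and parent.sex is Sex.FEMALE:
                issues.append(f"warning: father {parent_id!r} of {member.individual_id!r} is coded female")
            elif role == "mother" and parent.sex is Sex.MALE:
                issues.append(f"warning: mother {parent_id!r} of {member.individual_id!r} is coded male")

    # cycle detection on the child -> parent graph (iterative DFS)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {iid: WHITE for iid in members}
    for start in members:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        path: list[str] = []
        while stack:
            node, state = stack.pop()
            if state == 1:
                color[node] = BLACK
                path.pop()
                continue
            if color[node] == BLACK:
                continue
            if color[node] == GRAY:
                continue
            color[node] = GRAY
            path.append(node)
            stack.append((node, 1))
            member = members.get(node)
            parents = [p for p in (member.father_id, member.mother_id) if p is not None] if member else []
            for parent in parents:
                if parent not in members:
                    continue
                if color[parent] == GRAY:
                    chain = path[path.index(parent):] + [parent] if parent in path else [node, parent]
                    issues.append("ancestry cycle: " + " -> ".join(chain))
                elif color[parent] == WHITE:
                    stack.append((parent, 0))
    return issues


def mendelian_consistent(child: Call, father: Call, mother: Call) -> bool:
    """True iff the child call is producible from one allele of each parent.

    Any missing call makes the trio non-refutable (returns True).
    """
    if Call.MISSING in (child, father, mother):
        return True
    # alleles each parent can transmit, as alt-allele counts {0, 1}
    def gametes(call: Call) -> set[int]:
        return {0: {0}, 1: {0, 1}, 2: {1}}[int(call)]

    return any(a + b == int(child) for a in gametes(father) for b in gametes(mother))


class MissingGenotypeRule(str, Enum):
    NONINFORMATIVE = "noninformative"
    FAIL = "fail"


@dataclass(frozen=True)
class SegregationPolicy:
    """Tolerances of the dominant co-segregation check.

    Defaults encode strict full segregation: no unaffected carriers, no
    affected non-carriers, affected members heterozygous, missing genotypes
    non-informative.
    """

    require_het_in_affected: bool = True
    max_unaffected_carriers: int = 0
    max_affected_noncarriers: int = 0
    missing_genotype_rule: MissingGenotypeRule = MissingGenotypeRule.NONINFORMATIVE

    def __post_init__(self) -> None:
        if self.max_unaffected_carriers < 0 or self.max_affected_noncarriers < 0:
            raise ValueError("segregation tolerances must be non-negative")


# reason codes
AFFECTED_NONCARRIER = "AFFECTED_NONCARRIER"
UNAFFECTED_CARRIER = "UNAFFECTED_CARRIER"
AFFECTED_HOMALT = "AFFECTED_HOMALT"
NO_INFORMATIVE_GENOTYPES = "NO_INFORMATIVE_GENOTYPES"


@dataclass
class SegregationResult:
    variant: VariantKey
    family_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


def check_autosomal_dominant(
    variant: VariantKey,
    calls: Mapping[str, Call],
    pedigree: Pedigree,
    policy: SegregationPolicy = SegregationPolicy(),
) -> SegregationResult:
    """Evaluate dominant co-segregation of one variant in one family.

    Counts affected non-carriers and unaffected carriers among members with a
    known phenotype; unknown-phenotype members never contribute.  Missing
    genotypes are either skipped (``noninformative``) or counted as
    violations of their phenotype class (``fail``).  A variant with no
    informative affected genotype fails with ``NO_INFORMATIVE_GENOTYPES``.
    """
    unknown_ids = set(calls) - set(pedigree.members)
    if unknown_ids:
        raise ConsistencyError(
            f"calls reference ids absent from family {pedigree.family_id!r}: {sorted(unknown_ids)}"
        )

    count_fail = policy.missing_genotype_rule is MissingGenotypeRule.FAIL
    reasons: list[str] = []
    informative_affected = 0
    for member in pedigree.members.values():
        call = calls.get(member.individual_id, Call.MISSING)
        if member.affection is Affection.AFFECTED:
            if call is Call.MISSING:
                if count_fail:
                    reasons.append(AFFECTED_NONCARRIER)
                continue
            informative_affected += 1
            if call is Call.HOM_REF:
                reasons.append(AFFECTED_NONCARRIER)
            elif call is Call.HOM_ALT and policy.require_het_in_affected:
                reasons.append(AFFECTED_HOMALT)
        elif member.affection is Affection.UNAFFECTED:
            if call is Call.MISSING:
                if count_fail:
                    reasons.append(UNAFFECTED_CARRIER)
                continue
            if call in (Call.HET, Call.HOM_ALT):
                reasons.append(UNAFFECTED_CARRIER)
        # unknown phenotype: inert

    if informative_affected == 0:
        return SegregationResult(variant, pedigree.family_id, False, [NO_INFORMATIVE_GENOTYPES])

    passed = (
        reasons.count(AFFECTED_NONCARRIER) <= policy.max_affected_noncarriers
        and reasons.count(UNAFFECTED_CARRIER) <= policy.max_unaffected_carriers
        and AFFECTED_HOMALT not in reasons
    )
    return SegregationResult(variant, pedigree.family_id, passed, reasons)


def filter_segregating(
    variants: Sequence[VariantKey],
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    policy: SegregationPolicy = SegregationPolicy(),
) -> list[SegregationResult]:
    """Run the co-segregation check for every variant, preserving input order."""
    extra = set(genotypes.samples) - set(pedigree.members)
    if extra:
        raise ConsistencyError(
            f"genotype samples not in family {pedigree.family_id!r}: {sorted(extra)}"
        )
    results = []
    for variant in variants:
        calls = genotypes.calls_for(variant)
        results.append(check_autosomal_dominant(variant, calls, pedigree, policy))
    return results
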