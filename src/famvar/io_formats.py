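"""Readers and writers for the external formats the pipeline touches.

Formats handled: 6-column PED pedigrees, VCF v4.x genotypes (GT only, via
pysam), flat annotation TSVs with one row per (family, variant), GMT gene-set
libraries, and the candidate-report TSV that round-trips through the
annotation reader.

Also home to the shared domain types: :class:`VariantKey`,
:class:`AnnotatedVariant`, :class:`GenotypeMatrix` and the genotype-call /
consequence enumerations.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .exceptions import FormatError, ParseError, ValidationError

__all__ = [
    "VariantKey",
    "Consequence",
    "AnnotatedVariant",
    "Call",
    "GenotypeMatrix",
    "ANNOTATION_COLUMNS",
    "read_pedigree",
    "read_pedigrees",
    "read_variants",
    "read_annotations",
    "read_family_candidates",
    "read_gene_sets",
    "write_candidate_report",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


def _normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Bi-allelic variant identity: (chrom, pos, ref, alt) after normalization.

    Chromosome labels are stored without a ``chr`` prefix, positions are
    1-based, and alleles are upper-case A/C/G/T strings.  Equality and
    ordering are by the normalized tuple, so ``chr7`` and ``7`` compare
    equal.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _normalize_chrom(self.chrom))
        object.__setattr__(self, "pos", int(self.pos))
        object.__setattr__(self, "ref", str(self.ref).upper())
        object.__setattr__(self, "alt", str(self.alt).upper())
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not _ALLELE_RE.match(allele):
                raise ValidationError(f"{name} allele {allele!r} is not an A/C/G/T string")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # e.g. "7:127669537:A>G"
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class Consequence(str, Enum):
    """Coarse functional class of a variant."""

    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOPGAIN = "stopgain"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "Consequence":
        try:
            return cls(str(text).strip().lower())
        except ValueError as exc:
            raise ParseError(f"unknown consequence class {text!r}") from exc


# loss-of-function classes presumed damaging without missense predictors
LOF_CONSEQUENCES = frozenset({Consequence.FRAMESHIFT, Consequence.STOPGAIN, Consequence.SPLICING})


@dataclass
class AnnotatedVariant:
    """A variant plus the annotations the filters consume.

    ``maf_by_source`` maps a frequency-database name (e.g. ``gnomad``) to a
    population MAF; any source may be absent.  Predictor scores are optional
    — SIFT and PolyPhen2 live in [0, 1], CADD is PHRED-scaled (non-negative)
    and GERP++ is an unbounded conservation score.
    """

    key: VariantKey
    gene: str
    consequence: Consequence
    cdna_change: str = ""
    protein_change: str | None = None
    maf_by_source: dict[str, float] = field(default_factory=dict)
    sift: float | None = None
    polyphen2: float | None = None
    cadd: float | None = None
    gerp: float | None = None

    def __post_init__(self) -> None:
        for source, maf in self.maf_by_source.items():
            if not 0.0 <= maf <= 1.0:
                raise ValidationError(f"MAF for source {source!r} out of [0,1]: {maf}")
        for name in ("sift", "polyphen2"):
            score = getattr(self, name)
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValidationError(f"{name} score out of [0,1]: {score}")
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"CADD score must be non-negative: {self.cadd}")

    @property
    def aggregate_maf(self) -> float | None:
        """Max MAF over available sources (conservative for rarity); None if no source."""
        if not self.maf_by_source:
            return None
        return max(self.maf_by_source.values())


class Call(IntEnum):
    """Genotype call encoded as the alternate-allele count (-1 = missing)."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class GenotypeMatrix:
    """Calls for an ordered variant list over an ordered sample list."""

    def __init__(
        self,
        variants: Sequence[VariantKey],
        samples: Sequence[str],
        calls: np.ndarray | Sequence[Sequence[int]],
    ) -> None:
        self.variants = list(variants)
        self.samples = list(samples)
        self.calls = np.asarray(calls, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in genotype matrix")
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {v: i for i, v in enumerate(self.variants)}

    def call(self, variant: VariantKey, sample: str) -> Call:
        return Call(int(self.calls[self._variant_index[variant], self._sample_index[sample]]))

    def calls_for(self, variant: VariantKey) -> dict[str, Call]:
        """Per-sample calls for one variant."""
        row = self.calls[self._variant_index[variant]]
        return {s: Call(int(row[i])) for s, i in self._sample_index.items()}

    def __len__(self) -> int:
        return len(self.variants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PED


def read_pedigrees(path: str | Path):
    """Parse a 6-column PED file into one Pedigree per family id.

    Phenotype codes: 2 affected, 1 unaffected, 0 or -9 unknown.  A parent id
    of "0" marks a founder.  Raises :class:`ParseError` for malformed lines
    and :class:`ValidationError` for duplicate ids or dangling parent
    references.
    """
    from .pedigree import Pedigree, PedigreeMember, Sex, Affection

    sex_codes = {"1": Sex.MALE, "2": Sex.FEMALE}
    pheno_codes = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}

    members_by_family: dict[str, dict[str, PedigreeMember]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 whitespace-delimited columns, got {len(fields)}")
            fam, iid, father, mother, sex, pheno = fields[:6]
            if pheno not in pheno_codes:
                raise ParseError(f"{path}:{lineno}: unknown phenotype code {pheno!r}")
            member = PedigreeMember(
                individual_id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex_codes.get(sex, Sex.UNKNOWN),
                affection=pheno_codes[pheno],
            )
            fam_members = members_by_family.setdefault(fam, {})
            if iid in fam_members:
                raise ValidationError(f"{path}:{lineno}: duplicate individual id {iid!r} in family {fam!r}")
            fam_members[iid] = member

    pedigrees = {}
    for fam, fam_members in members_by_family.items():
        for member in fam_members.values():
            for parent in (member.father_id, member.mother_id):
                if parent is not None and parent not in fam_members:
                    raise ValidationError(
                        f"family {fam!r}: member {member.individual_id!r} references absent parent {parent!r}"
                    )
        pedigrees[fam] = Pedigree(family_id=fam, members=fam_members)
    return pedigrees


def read_pedigree(path: str | Path):
    """Parse a PED file that must contain exactly one family."""
    pedigrees = read_pedigrees(path)
    if len(pedigrees) != 1:
        raise ValidationError(f"{path}: expected exactly one family, found {sorted(pedigrees)}")
    return next(iter(pedigrees.values()))


# ---------------------------------------------------------------------------
# VCF


def _split_gt(gt: tuple, alt_index: int) -> Call:
    # pysam returns GT as a tuple of allele indices, None for '.'
    if gt is None or any(a is None for a in gt):
        return Call.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    return Call(min(n_alt, 2))


def read_variants(path: str | Path) -> tuple[list[VariantKey], GenotypeMatrix]:
    """Read GT calls from a VCF; multi-allelic records are split to bi-allelic.

    Phased and unphased separators are equivalent; for a split allele every
    sample call counts copies of that allele only ("1/2" is het for each of
    the two splits).
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        keys: list[VariantKey] = []
        rows: list[list[int]] = []
        for record in vcf:
            if "GT" not in record.format:
                raise FormatError(f"{path}: record {record.chrom}:{record.pos} has no GT in FORMAT")
            alts = record.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or not _ALLELE_RE.match(alt.upper()):
                    continue  # symbolic/spanning alleles are not variants we filter
                keys.append(VariantKey(record.chrom, record.pos, record.ref, alt))
                rows.append(
                    [int(_split_gt(record.samples[s].get("GT"), alt_index)) for s in samples]
                )
    matrix = GenotypeMatrix(keys, samples, np.array(rows, dtype=np.int8).reshape(len(keys), len(samples)))
    return keys, matrix


# ---------------------------------------------------------------------------
# Annotation TSV

ANNOTATION_COLUMNS = [
    "family",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "cdna",
    "protein",
    "gnomad_maf",
    "sift",
    "polyphen2",
    "cadd",
    "gerp",
]

_NUMERIC_COLUMNS = ("gnomad_maf", "sift", "polyphen2", "cadd", "gerp")


def _parse_optional_float(value, column: str, lineno: int) -> float | None:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan"):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"row {lineno}: column {column!r} is not numeric or NA: {text!r}") from exc


def _parse_annotation_table(path: str | Path) -> list[tuple[str, AnnotatedVariant]]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    records: list[tuple[str, AnnotatedVariant]] = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        maf = _parse_optional_float(row.gnomad_maf, "gnomad_maf", lineno)
        protein = str(row.protein).strip()
        variant = AnnotatedVariant(
            key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
            gene=str(row.gene).strip(),
            consequence=Consequence.parse(row.consequence),
            cdna_change=str(row.cdna).strip(),
            protein_change=None if protein.lower() in ("", "na") else protein,
            maf_by_source={} if maf is None else {"gnomad": maf},
            sift=_parse_optional_float(row.sift, "sift", lineno),
            polyphen2=_parse_optional_float(row.polyphen2, "polyphen2", lineno),
            cadd=_parse_optional_float(row.cadd, "cadd", lineno),
            gerp=_parse_optional_float(row.gerp, "gerp", lineno),
        )
        records.append((str(row.family).strip(), variant))
    return records


def read_annotations(path: str | Path) -> list[AnnotatedVariant]:
    """Read an annotation TSV; "NA" (case-insensitive) and "" denote missing."""
    return [variant for _, variant in _parse_annotation_table(path)]


def read_family_candidates(path: str | Path) -> dict[str, list[AnnotatedVariant]]:
    """Read an annotation TSV grouped by its family-label column (order kept)."""
    grouped: dict[str, list[AnnotatedVariant]] = {}
    for family, variant in _parse_annotation_table(path):
        grouped.setdefault(family, []).append(variant)
    return grouped


def _format_number(value: float | None) -> str:
    if value is None:
        return "NA"
    # 12 significant digits so reports round-trip numerically
    return f"{value:.12g}"


def write_candidate_report(
    candidates: Iterable[tuple[str, AnnotatedVariant]],
    path: str | Path,
) -> None:
    """Write (family, variant) rows as a TSV that read_annotations can re-read."""
    rows = []
    for family, v in candidates:
        rows.append(
            {
                "family": family,
                "gene": v.gene,
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "consequence": v.consequence.value,
                "cdna": v.cdna_change,
                "protein": v.protein_change if v.protein_change is not None else "NA",
                "gnomad_maf": _format_number(v.maf_by_source.get("gnomad")),
                "sift": _format_number(v.sift),
                "polyphen2": _format_number(v.polyphen2),
                "cadd": _format_number(v.cadd),
                "gerp": _format_number(v.gerp),
            }
        )
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set library: term, description, member genes.

    Gene symbols are upper-cased; duplicate genes within a line collapse into
    the set; a repeated term is an error (ambiguous library).
    """
    library: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            term = fields[0].strip()
            if term in library:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            library[term] = genes
    return library
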