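"""Synthetic cohort generation and packaged fixture tables.

The simulator emulates the statistical structure of a two-stage familial
rare-variant study: multi-generation pedigrees, a single fully-penetrant
dominant causal variant introduced heterozygously into one founder per
family and transmitted by Mendelian gamete draws, background variants at
Hardy-Weinberg equilibrium with a mixed common/rare MAF spectrum, and
per-variant predictor annotations drawn from causal-like or benign-like
score ranges anchored to the filter thresholds.

``make_paper_fixture`` returns small annotation tables transcribing the
published candidate-variant tables of the rosacea family study this
pipeline reimplements (6 discovery variants, 12 validation variants, and
three recurrent PCDHA5 variants), used throughout the test-suite and the
worked examples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io_formats import (
    ANNOTATION_COLUMNS,
    AnnotatedVariant,
    Call,
    Consequence,
    GenotypeMatrix,
    VariantKey,
    write_candidate_report,
)
from .pedigree import Affection, Pedigree, PedigreeMember, Sex

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "SimulatedCohort",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_annotations",
    "simulate_cohort",
    "write_cohort",
    "make_paper_fixture",
    "background_survival_probability",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; ``seed`` fixes every random draw.

    Defaults mirror the study design the pipeline targets: 3 large
    discovery families (3 generations, 19 members each) and 49 small
    validation families, one fully-penetrant heterozygous dominant causal
    variant per family, causal variants absent from population frequency
    databases, and background variants drawn half from a common and half
    from a rare MAF stratum.
    """

    n_large_families: int = 3
    n_small_families: int = 49
    large_family_generations: int = 3
    members_per_large_family: int = 19
    small_family_generations: int = 2
    members_per_small_family: int = 6
    causal_gene: str = "CAUSAL"
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    n_background_variants: int = 100
    background_common_weight: float = 0.5  # P(common stratum, MAF ~ U(0.01, 0.5))
    causal_maf: float = 0.0
    causal_score_noise: float = 0.1  # P(background variant drawing causal-like scores)
    consequence_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.40,
            "synonymous": 0.30,
            "other": 0.12,
            "splicing": 0.06,
            "frameshift": 0.06,
            "stopgain": 0.06,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "background_common_weight", "causal_maf", "causal_score_noise"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]: {value}")
        for name in ("n_large_families", "n_small_families", "n_background_variants"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(sum(self.consequence_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("consequence_probs must sum to 1")


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    causal_key: VariantKey
    causal_gene: str


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    families: list[SimulatedFamily]
    annotations: list[tuple[str, AnnotatedVariant]]  # (family_id, variant)

    @property
    def truth(self) -> dict[str, VariantKey]:
        """family_id -> causal variant key."""
        return {f.pedigree.family_id: f.causal_key for f in self.families}


# ---------------------------------------------------------------------------
# pedigree structure


def _minimum_members(generations: int) -> int:
    # founding couple + one reproducing child (with married-in spouse) per
    # intermediate generation + one terminal child
    if generations < 2:
        return 3
    return 2 + 2 * (generations - 2) + 1


def simulate_pedigree(cfg: SimulationConfig, family_index: int, *, small: bool = False) -> Pedigree:
    """Build one connected multi-generation family, deterministically.

    The founding couple sits in generation I; in each later non-terminal
    generation roughly a third of the allocated members are married-in
    spouses of the previous generation's children.  Affection status is
    assigned later from simulated genotypes.
    """
    generations = cfg.small_family_generations if small else cfg.large_family_generations
    target = cfg.members_per_small_family if small else cfg.members_per_large_family
    if generations < 2:
        raise ConfigurationError("a pedigree needs at least 2 generations")
    if target < _minimum_members(generations):
        raise ConfigurationError(
            f"{target} members cannot span {generations} generations "
            f"(minimum {_minimum_members(generations)})"
        )
    family_id = ("S" if small else "L") + str(family_index + 1)
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]

    members: dict[str, PedigreeMember] = {}

    def add(gen: int, idx: int, father: str | None, mother: str | None, sex: Sex) -> str:
        iid = f"{roman[gen - 1]}-{idx}"
        members[iid] = PedigreeMember(iid, father, mother, sex)
        return iid

    father0 = add(1, 1, None, None, Sex.MALE)
    mother0 = add(1, 2, None, None, Sex.FEMALE)
    couples = [(father0, mother0)]
    count = 2
    for gen in range(2, generations + 1):
        remaining_gens = generations - gen + 1
        terminal = gen == generations
        if terminal:
            budget = target - count
        else:
            # a non-terminal generation needs at least one child + one spouse
            budget = max(2, (target - count) // remaining_gens)
        n_spouses = 0 if terminal else max(1, budget // 3)
        n_children = budget - n_spouses
        idx = 1
        children: list[tuple[str, Sex]] = []
        for j in range(n_children):
            f, m = couples[j % len(couples)]
            sex = Sex.MALE if j % 2 == 0 else Sex.FEMALE
            children.append((add(gen, idx, f, m, sex), sex))
            idx += 1
        next_couples = []
        for j in range(n_spouses):
            child_id, child_sex = children[j % len(children)]
            spouse_sex = Sex.FEMALE if child_sex is Sex.MALE else Sex.MALE
            spouse = add(gen, idx, None, None, spouse_sex)
            idx += 1
            couple = (child_id, spouse) if child_sex is Sex.MALE else (spouse, child_id)
            next_couples.append(couple)
        couples = next_couples if next_couples else couples
        count += n_children + n_spouses
    return Pedigree(family_id=family_id, members=members)


# ---------------------------------------------------------------------------
# genotypes

_BASES = np.array(list("ACGT"))


def _transmit(rng: np.random.Generator, parent_call: int) -> int:
    """One gamete (alt-allele count 0/1) from a parent genotype."""
    if parent_call == 0:
        return 0
    if parent_call == 2:
        return 1
    return int(rng.integers(0, 2))


def _drop_genotypes(
    rng: np.random.Generator,
    pedigree: Pedigree,
    founder_calls: dict[str, int],
) -> dict[str, int]:
    """Gene-drop founder genotypes through the pedigree, parents first."""
    calls: dict[str, int] = {}
    pending = dict(pedigree.members)
    while pending:
        progressed = False
        for iid, member in list(pending.items()):
            if member.is_founder:
                calls[iid] = founder_calls[iid]
            elif member.father_id in calls and member.mother_id in calls:
                calls[iid] = _transmit(rng, calls[member.father_id]) + _transmit(
                    rng, calls[member.mother_id]
                )
            else:
                continue
            del pending[iid]
            progressed = True
        if not progressed:
            raise ValidationError(f"family {pedigree.family_id}: unresolvable parentage")
    return calls


def simulate_genotypes(
    pedigree: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    causal_key: VariantKey,
    background_keys: Sequence[VariantKey],
    background_mafs: Sequence[float],
) -> tuple[GenotypeMatrix, dict[str, Affection]]:
    """Simulate calls for the causal and background variants plus affection.

    The causal variant enters heterozygously in the first founder of the
    founding couple; background variants give each founder a Hardy-Weinberg
    genotype at the variant's MAF.  Affection is penetrance-Bernoulli for
    carriers and phenocopy-Bernoulli for non-carriers.
    """
    founders = [m.individual_id for m in pedigree.founders]
    first_founder = min(founders)  # I-1, deterministic

    causal_founder_calls = {iid: (1 if iid == first_founder else 0) for iid in founders}
    causal_calls = _drop_genotypes(rng, pedigree, causal_founder_calls)

    rows = [list(causal_calls[s] for s in pedigree.members)]
    for key, maf in zip(background_keys, background_mafs):
        probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        founder_calls = {iid: int(rng.choice(3, p=probs)) for iid in founders}
        calls = _drop_genotypes(rng, pedigree, founder_calls)
        rows.append([calls[s] for s in pedigree.members])

    samples = list(pedigree.members)
    matrix = GenotypeMatrix([causal_key, *background_keys], samples, np.array(rows, dtype=np.int8))

    affection: dict[str, Affection] = {}
    for iid in samples:
        carrier = causal_calls[iid] > 0
        p_affected = cfg.penetrance if carrier else cfg.phenocopy_rate
        affection[iid] = Affection.AFFECTED if rng.random() < p_affected else Affection.UNAFFECTED
    return matrix, affection


# ---------------------------------------------------------------------------
# annotations

_CAUSAL_RANGES = {"sift": (0.0, 0.05), "polyphen2": (0.825, 1.0), "cadd": (20.0, 40.0), "gerp": (2.0, 6.0)}
_BENIGN_RANGES = {"sift": (0.05, 1.0), "polyphen2": (0.0, 0.825), "cadd": (0.0, 20.0), "gerp": (-2.0, 2.0)}


def _draw_scores(rng: np.random.Generator, causal_like: bool) -> dict[str, float]:
    ranges = _CAUSAL_RANGES if causal_like else _BENIGN_RANGES
    return {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}


def simulate_annotations(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    family_id: str,
    causal_key: VariantKey,
    causal_gene: str,
    background_keys: Sequence[VariantKey],
    background_mafs: Sequence[float],
) -> list[tuple[str, AnnotatedVariant]]:
    """Annotate one family's variants with consequences, MAFs and scores.

    The causal variant is missense with causal-like scores and
    ``causal_maf`` (0 means absent from every frequency source).
    Background variants draw a consequence class, carry their simulated
    population MAF, and receive benign-like scores except for a
    ``causal_score_noise`` fraction of annotation noise.  LoF and
    non-missense classes carry no missense predictor scores, mirroring how
    annotation tools behave.
    """
    records: list[tuple[str, AnnotatedVariant]] = []
    causal_scores = _draw_scores(rng, causal_like=True)
    records.append(
        (
            family_id,
            AnnotatedVariant(
                key=causal_key,
                gene=causal_gene,
                consequence=Consequence.MISSENSE,
                cdna_change="c.SIM",
                maf_by_source={} if cfg.causal_maf == 0 else {"gnomad": cfg.causal_maf},
                **causal_scores,
            ),
        )
    )
    classes = list(cfg.consequence_probs)
    probs = np.array([cfg.consequence_probs[c] for c in classes])
    for i, (key, maf) in enumerate(zip(background_keys, background_mafs)):
        consequence = Consequence(classes[int(rng.choice(len(classes), p=probs))])
        causal_like = rng.random() < cfg.causal_score_noise
        scores = _draw_scores(rng, causal_like)
        if consequence is not Consequence.MISSENSE:
            scores = {k: None for k in scores}  # predictors score missense substitutions only
        records.append(
            (
                family_id,
                AnnotatedVariant(
                    key=key,
                    gene=f"BG{key.chrom}_{key.pos}",
                    consequence=consequence,
                    cdna_change="c.SIM",
                    maf_by_source={"gnomad": maf},
                    **scores,
                ),
            )
        )
    return records


def background_survival_probability(cfg: SimulationConfig) -> float:
    """Analytic probability that a background variant passes the annotation
    filter (consequence x rarity x consensus) under the generator's model.

    P = P(MAF < 0.01) * [P(LoF class) + P(missense) * P(causal-like scores)].
    Rare-stratum MAFs pass almost surely; common-stratum MAFs fail.
    Synonymous/other classes fail the consequence stage; LoF classes bypass
    the consensus; missense needs causal-like scores.
    """
    p_rare = 1.0 - cfg.background_common_weight
    probs = cfg.consequence_probs
    p_lof = probs.get("frameshift", 0.0) + probs.get("stopgain", 0.0) + probs.get("splicing", 0.0)
    p_missense = probs.get("missense", 0.0)
    return p_rare * (p_lof + p_missense * cfg.causal_score_noise)


# ---------------------------------------------------------------------------
# cohort orchestration


def _variant_keys_for_family(
    rng: np.random.Generator, family_index: int, n_background: int
) -> tuple[VariantKey, list[VariantKey]]:
    chrom = str(family_index % 22 + 1)
    causal = VariantKey(chrom, 1_000_000 + family_index, "A", "G")
    background = []
    for i in range(n_background):
        ref, alt = rng.choice(4, size=2, replace=False)
        background.append(
            VariantKey(str(i % 22 + 1), 2_000_000 + family_index * 1_000_000 + i, _BASES[ref], _BASES[alt])
        )
    return causal, background


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate the full two-stage cohort: pedigrees, genotypes, annotations."""
    rng = np.random.default_rng(cfg.seed)
    families: list[SimulatedFamily] = []
    annotations: list[tuple[str, AnnotatedVariant]] = []
    specs = [(i, False) for i in range(cfg.n_large_families)] + [
        (cfg.n_large_families + i, True) for i in range(cfg.n_small_families)
    ]
    for family_index, small in specs:
        pedigree = simulate_pedigree(cfg, family_index, small=small)
        causal_key, background_keys = _variant_keys_for_family(rng, family_index, cfg.n_background_variants)
        common = rng.random(cfg.n_background_variants) < cfg.background_common_weight
        background_mafs = np.where(
            common,
            rng.uniform(0.01, 0.5, cfg.n_background_variants),
            rng.uniform(0.0, 0.01, cfg.n_background_variants),
        )
        matrix, affection = simulate_genotypes(
            pedigree, cfg, rng, causal_key, background_keys, background_mafs
        )
        members = {
            iid: dataclasses.replace(m, affection=affection[iid])
            for iid, m in pedigree.members.items()
        }
        pedigree = Pedigree(family_id=pedigree.family_id, members=members)
        causal_gene = f"{cfg.causal_gene}_{pedigree.family_id}"
        annotations.extend(
            simulate_annotations(
                cfg, rng, pedigree.family_id, causal_key, causal_gene, background_keys, background_mafs
            )
        )
        families.append(SimulatedFamily(pedigree, matrix, causal_key, causal_gene))
    return SimulatedCohort(config=cfg, families=families, annotations=annotations)


# ---------------------------------------------------------------------------
# on-disk cohort


_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
_CALL_OUT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_ped(pedigree: Pedigree, path: Path) -> None:
    with open(path, "w") as handle:
        for m in pedigree.members.values():
            handle.write(
                " ".join(
                    [
                        pedigree.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_OUT[m.sex],
                        _PHENO_OUT[m.affection],
                    ]
                )
                + "\n"
            )


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    # fixed serialization of the bi-allelic dialect read_variants consumes
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in matrix.variants}, key=lambda c: (len(c), c)):
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples) + "\n")
        order = sorted(range(len(matrix.variants)), key=lambda i: (len(matrix.variants[i].chrom), matrix.variants[i].chrom, matrix.variants[i].pos))
        for i in order:
            v = matrix.variants[i]
            gts = "\t".join(_CALL_OUT[int(c)] for c in matrix.calls[i])
            handle.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write PED + VCF + annotation TSV per family, plus a truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_family: dict[str, list[tuple[str, AnnotatedVariant]]] = {}
    for fam_id, variant in cohort.annotations:
        by_family.setdefault(fam_id, []).append((fam_id, variant))
    for family in cohort.families:
        fam_id = family.pedigree.family_id
        _write_ped(family.pedigree, outdir / f"{fam_id}.ped")
        _write_vcf(family.genotypes, outdir / f"{fam_id}.vcf")
        write_candidate_report(by_family.get(fam_id, []), outdir / f"{fam_id}.annotations.tsv")
    truth = pd.DataFrame(
        [
            {
                "family": f.pedigree.family_id,
                "causal_gene": f.causal_gene,
                "causal_variant": str(f.causal_key),
            }
            for f in cohort.families
        ]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixtures transcribing the published candidate tables

# columns: family, gene, chrom, pos, ref, alt, consequence, cdna, protein,
#          gnomad_maf, sift, polyphen2  (CADD / GERP++ were not printed)
_TABLE1_ROWS = [
    ("1", "LRRC4", "7", 127669537, "A", "G", "missense", "c.T1157C", "p.L386P", 0.000008244, 0.025, 0.980),
    ("2", "SH3PXD2A", "10", 105362610, "G", "A", "missense", "c.C2281T", "p.R761C", 0.0000907, 0.000, 0.997),
    ("2", "MKI67", "10", 129914272, "C", "T", "splicing", "c.401-1G>A", None, 0.0003, None, None),
    ("2", "KMT2C", "7", 151845490, "G", "T", "missense", "c.C13522A", "p.P4508T", 0.00003295, 0.041, 0.999),
    ("3", "SLC26A8", "6", 35922970, "C", "T", "missense", "c.G1876A", "p.V626I", 0.0004, 0.007, 0.998),
    ("3", "C1orf106", "1", 200880676, "G", "C", "missense", "c.G1055C", "p.C352S", 0.00002488, 0.018, 0.987),
]

_TABLE2_ROWS = [
    ("42", "LRRC43", "12", 122684858, "T", "C", "missense", "c.T1472C", "p.V491A", None, 0.003, 0.915),
    ("332", "LRRC44", "1", 74575239, "T", "C", "splicing", "c.708-2A>G", None, None, None, None),
    ("94", "LRRC47", "1", 3700588, "T", "G", "missense", "c.A1282C", "p.K428Q", None, 0.005, 0.918),
    ("313", "LRRC55", "11", 56949659, "C", "T", "missense", "c.C292T", "p.R98W", None, 0.017, 0.997),
    ("147", "LRRCC1", "8", 56949659, "G", "A", "missense", "c.G1931A", "p.R644H", 0.0008, 0.000, 0.999),
    ("147", "LRRCC1", "8", 86050476, "C", "G", "stopgain", "c.C2700G", "p.Y900X", 0.0005, None, None),
    ("311", "LRRD1", "7", 91788389, "G", "C", "stopgain", "c.C2046G", "p.Y682X", 0.0004, None, None),
    ("314", "LRRD1", "7", 91779953, "T", "C", "missense", "c.A2173G", "p.I725V", 0.005, 0.024, 0.984),
    ("399", "LRRD1", "7", 91779953, "T", "C", "missense", "c.A2173G", "p.I725V", 0.005, 0.024, 0.984),
    ("48", "LRRTM4", "2", 77746619, "T", "C", "missense", "c.A379G", "p.N127D", 0.0015, 0.004, 1.0),
    ("312", "SH3PXD2A", "10", 105363285, "C", "T", "missense", "c.G1606A", "p.G536S", 0.0001, 0.037, 1.0),
    ("319", "SLC26A8", "6", 35945067, "A", "G", "missense", "c.T772C", "p.S258P", 0.00001759, 0.006, 0.999),
]

# Only cDNA/protein changes and families were printed for the recurrent
# PCDHA5 variants; genomic positions here are synthetic placeholders
# (chr5, 140200000 + cDNA offset) — alleles follow the printed cDNA changes.
_PCDHA5_ROWS = [
    ("209", "PCDHA5", "5", 140201195, "A", "C", "missense", "c.A1195C", "p.T399", None, None, None),
    ("213", "PCDHA5", "5", 140201966, "C", "G", "missense", "c.C1966G", "p.P656A", None, None, None),
    ("313", "PCDHA5", "5", 140200880, "A", "T", "missense", "c.A880T", "p.I294F", None, None, None),
]

_FIXTURES = {"table1": _TABLE1_ROWS, "table2": _TABLE2_ROWS, "pcdha5": _PCDHA5_ROWS}


def make_paper_fixture(which: str) -> pd.DataFrame:
    """Return one packaged fixture as an annotation-schema DataFrame.

    ``table1``: the 6 discovery-stage candidate variants (large families,
    WGS).  ``table2``: the 12 validation-stage candidates (small families,
    WES).  ``pcdha5``: the three recurrent PCDHA5 variants with their family
    ids (synthetic genomic coordinates, printed alleles and changes).
    """
    try:
        rows = _FIXTURES[which]
    except KeyError as exc:
        raise ValidationError(f"unknown fixture {which!r}; choose from {sorted(_FIXTURES)}") from exc
    frame = pd.DataFrame(
        rows,
        columns=[
            "family", "gene", "chrom", "pos", "ref", "alt", "consequence",
            "cdna", "protein", "gnomad_maf", "sift", "polyphen2",
        ],
    )
    frame["cadd"] = None
    frame["gerp"] = None
    return frame[ANNOTATION_COLUMNS]


def fixture_candidates(which: str) -> dict[str, list[AnnotatedVariant]]:
    """Fixture rows as AnnotatedVariant lists grouped by family id."""
    frame = make_paper_fixture(which)
    grouped: dict[str, list[AnnotatedVariant]] = {}
    def opt(value) -> float | None:
        return None if pd.isna(value) else float(value)

    for row in frame.itertuples(index=False):
        variant = AnnotatedVariant(
            key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
            gene=row.gene,
            consequence=Consequence.parse(row.consequence),
            cdna_change=row.cdna,
            protein_change=None if pd.isna(row.protein) else row.protein,
            maf_by_source={} if pd.isna(row.gnomad_maf) else {"gnomad": float(row.gnomad_maf)},
            sift=opt(row.sift),
            polyphen2=opt(row.polyphen2),
        )
        grouped.setdefault(str(row.family), []).append(variant)
    return grouped
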