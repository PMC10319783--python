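"""Rarity, consequence and deleteriousness-consensus filtering.

Second and third stages of the discovery filter: keep protein-altering
classes (missense, frameshift, stopgain, splice site), require a population
minor allele frequency below 1% in every frequency database, and require a
consensus of in-silico predictors (SIFT < 0.05, PolyPhen2 > 0.825,
CADD > 20, GERP++ > 2; damaging in at least 3 of the 4).  Loss-of-function
classes bypass the missense-oriented predictor consensus, and when fewer
than four predictors are annotated the consensus requirement adapts to the
number available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .exceptions import ValidationError
from .io_formats import AnnotatedVariant, Consequence, LOF_CONSEQUENCES, VariantKey

__all__ = [
    "FilterConfig",
    "PredictorCall",
    "PredictorCalls",
    "maf_pass",
    "consequence_pass",
    "predictor_calls",
    "consensus_pass",
    "composite_filter",
]

DEFAULT_ALLOWED = frozenset(
    {Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.STOPGAIN, Consequence.SPLICING}
)


@dataclass(frozen=True)
class FilterConfig:
    """Every threshold and policy of the rarity/deleteriousness filter.

    Inequalities are strict exactly as stated: MAF < ``maf_threshold``,
    SIFT < ``sift_threshold``, PolyPhen2 > ``polyphen2_threshold``,
    CADD > ``cadd_threshold`` (PHRED scale), GERP++ > ``gerp_threshold``.
    """

    maf_threshold: float = 0.01
    sift_threshold: float = 0.05
    polyphen2_threshold: float = 0.825
    cadd_threshold: float = 20.0
    gerp_threshold: float = 2.0
    min_damaging: int = 3
    allowed_consequences: frozenset[Consequence] = DEFAULT_ALLOWED
    lof_bypass_consequences: frozenset[Consequence] = frozenset(LOF_CONSEQUENCES)
    missing_maf_is_rare: bool = True
    maf_aggregation: str = "max_over_sources"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise ValidationError(f"maf_threshold out of [0,1]: {self.maf_threshold}")
        if not 0.0 <= self.sift_threshold <= 1.0:
            raise ValidationError(f"sift_threshold out of [0,1]: {self.sift_threshold}")
        if not 0.0 <= self.polyphen2_threshold <= 1.0:
            raise ValidationError(f"polyphen2_threshold out of [0,1]: {self.polyphen2_threshold}")
        if not 1 <= self.min_damaging <= 4:
            raise ValidationError(f"min_damaging must be in [1,4]: {self.min_damaging}")
        if self.maf_aggregation != "max_over_sources":
            raise ValidationError(f"unknown maf_aggregation {self.maf_aggregation!r}")


class PredictorCall(str, Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    UNAVAILABLE = "unavailable"


PREDICTORS = ("SIFT", "PolyPhen2", "CADD", "GERP++")


@dataclass(frozen=True)
class PredictorCalls:
    """Damaging/benign/unavailable call for each of the four predictors."""

    sift: PredictorCall
    polyphen2: PredictorCall
    cadd: PredictorCall
    gerp: PredictorCall

    def as_dict(self) -> dict[str, PredictorCall]:
        return dict(zip(PREDICTORS, (self.sift, self.polyphen2, self.cadd, self.gerp)))

    @property
    def n_available(self) -> int:
        return sum(c is not PredictorCall.UNAVAILABLE for c in self.as_dict().values())

    @property
    def n_damaging(self) -> int:
        return sum(c is PredictorCall.DAMAGING for c in self.as_dict().values())


def maf_pass(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff the aggregate MAF (max over sources) is below the threshold.

    A variant absent from every frequency database passes when
    ``missing_maf_is_rare`` (the default): novelty is evidence of rarity.
    """
    aggregate = v.aggregate_maf
    if aggregate is None:
        return cfg.missing_maf_is_rare
    return aggregate < cfg.maf_threshold


def consequence_pass(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> bool:
    return v.consequence in cfg.allowed_consequences


def _call(score: float | None, damaging: bool) -> PredictorCall:
    if score is None:
        return PredictorCall.UNAVAILABLE
    return PredictorCall.DAMAGING if damaging else PredictorCall.BENIGN


def predictor_calls(v: AnnotatedVariant, cfg: FilterConfig = FilterConfig()) -> PredictorCalls:
    """Map each available score to damaging/benign by its strict inequality."""
    for name, score in (("sift", v.sift), ("polyphen2", v.polyphen2)):
        if score is not None and not 0.0 <= score <= 1.0:
            raise ValidationError(f"{name} score out of [0,1]: {score}")
    return PredictorCalls(
        sift=_call(v.sift, v.sift is not None and v.sift < cfg.sift_threshold),
        polyphen2=_call(v.polyphen2, v.polyphen2 is not None and v.polyphen2 > cfg.polyphen2_threshold),
        cadd=_call(v.cadd, v.cadd is not None and v.cadd > cfg.cadd_threshold),
        gerp=_call(v.gerp, v.gerp is not None and v.gerp > cfg.gerp_threshold),
    )


def consensus_pass(
    calls: PredictorCalls,
    consequence: Consequence,
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """At-least-3-of-4 predictor consensus, adapted to availability.

    Loss-of-function classes bypass the consensus entirely.  Otherwise the
    requirement is ``min(min_damaging, n_available)`` (at least 1); a
    missense variant with no predictor annotated fails.
    """
    if consequence in cfg.lof_bypass_consequences:
        return True
    k = calls.n_available
    if k == 0:
        return False
    required = max(1, min(cfg.min_damaging, k))
    return calls.n_damaging >= required


def composite_filter(
    variants: Sequence[AnnotatedVariant],
    segregation: Mapping[VariantKey, bool] | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> list[AnnotatedVariant]:
    """Apply segregation + consequence + rarity + consensus; keep input order.

    A variant absent from the segregation map is treated as segregating
    (annotation-only inputs carry no genotypes).  The retained set is
    independent of stage evaluation order — every stage is a pure predicate.
    """
    segregation = segregation or {}
    retained = []
    for v in variants:
        if not segregation.get(v.key, True):
            continue
        if not consequence_pass(v, cfg):
            continue
        if not maf_pass(v, cfg):
            continue
        if not consensus_pass(predictor_calls(v, cfg), v.consequence, cfg):
            continue
        retained.append(v)
    return retained
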