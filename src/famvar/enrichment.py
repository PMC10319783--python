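"""Gene-set enrichment by the two-sided Fisher exact test.

For each library term a 2x2 table is built over a gene universe (candidates
in/out of the set vs the rest of the universe) and tested with the exact
hypergeometric probability-mass rule: the two-sided p-value sums the
probabilities of all tables with the same margins that are no more probable
than the observed one.  The implementation enumerates the hypergeometric
support with exact integer arithmetic (``math.comb``), so ties are resolved
exactly; a relative tolerance guards the comparison when callers supply
float-derived tables.  Benjamini-Hochberg q-values are reported alongside
raw p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import ConsistencyError, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_two_sided",
    "enrich",
    "adjust_bh",
]

#: relative tolerance for probability ties in the two-sided sum
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = candidates in set, b = candidates out, c = other universe
    genes in set, d = remainder."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative cell {name} in 2x2 table: {getattr(self, name)}")


def fisher_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the probability-mass rule.

    With margins fixed, the first cell k follows a hypergeometric law with
    integer weights w(k) = C(r1, k) * C(r2, c1 - k) over the support; the
    p-value is the (exact-rational) sum of weights w(k) <= w(a), evaluated
    with integer arithmetic and returned as a float in (0, 1].
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d  # row margins
    c1 = a + c             # first column margin
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # a degenerate margin admits a single table
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    # integer tie bound implementing w <= w_obs * (1 + TIE_RTOL)
    bound_num = w_obs * (10**7 + 1)
    tail = sum(w for w in weights if w * 10**7 <= bound_num)
    total = math.comb(n, c1)
    return min(1.0, tail / total)


@dataclass
class EnrichmentResult:
    term: str
    overlap: frozenset[str]
    table: ContingencyTable2x2
    p_value: float
    q_value: float


def enrich(
    candidates: Iterable[str],
    library: Mapping[str, frozenset[str] | set[str]],
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every library term for candidate over/under-representation.

    The universe defaults to the union of all library genes.  Candidates
    must lie within the universe; each term's gene set is restricted to the
    universe before the table is built.  Terms with no universe gene are
    omitted.  Results are sorted by p ascending, ties broken by term.
    """
    candidate_set = {str(g).upper() for g in candidates}
    if not candidate_set:
        raise ValidationError("empty candidate gene set")
    if not library:
        raise ValidationError("empty gene-set library")
    if universe is None:
        universe_set = set().union(*library.values())
    else:
        universe_set = {str(g).upper() for g in universe}
    outside = candidate_set - universe_set
    if outside:
        raise ConsistencyError(f"candidate genes outside the universe: {sorted(outside)}")

    n_universe = len(universe_set)
    n_candidates = len(candidate_set)
    results: list[EnrichmentResult] = []
    for term in sorted(library):
        term_genes = {str(g).upper() for g in library[term]} & universe_set
        if not term_genes:
            continue
        overlap = candidate_set & term_genes
        a = len(overlap)
        b = n_candidates - a
        c = len(term_genes) - a
        d = n_universe - n_candidates - c
        table = ContingencyTable2x2(a, b, c, d)
        results.append(
            EnrichmentResult(
                term=term,
                overlap=frozenset(overlap),
                table=table,
                p_value=fisher_two_sided(table),
                q_value=math.nan,
            )
        )
    qs = adjust_bh([r.p_value for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q_value = q
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1) | ~np.isfinite(ps)):
        raise ValidationError("p-values must lie in [0,1]")
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    return [float(q) for q in qs]
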