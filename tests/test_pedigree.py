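"""Pedigree validation, Mendelian logic, and dominant co-segregation."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar.exceptions import ConsistencyError
from famvar.io_formats import Call, GenotypeMatrix, VariantKey
from famvar.pedigree import (
    AFFECTED_HOMALT,
    AFFECTED_NONCARRIER,
    NO_INFORMATIVE_GENOTYPES,
    UNAFFECTED_CARRIER,
    Affection,
    MissingGenotypeRule,
    Pedigree,
    PedigreeMember,
    SegregationPolicy,
    Sex,
    check_autosomal_dominant,
    filter_segregating,
    mendelian_consistent,
    validate,
)

KEY = VariantKey("1", 100, "A", "G")


# ---------------------------------------------------------------------------
# validate


def test_validate_reports_cycle_with_id_chain():
    members = {
        "A": PedigreeMember("A", "C", None, Sex.MALE, Affection.AFFECTED),
        "B": PedigreeMember("B", "A", None, Sex.MALE, Affection.UNKNOWN),
        "C": PedigreeMember("C", "B", None, Sex.MALE, Affection.UNKNOWN),
    }
    issues = validate(Pedigree("F", members))
    assert any("cycle" in issue for issue in issues)


def test_validate_clean_three_generations(six_member_pedigree):
    assert validate(six_member_pedigree) == []


def test_validate_sex_inconsistency_is_warning():
    members = {
        "A": PedigreeMember("A", None, None, Sex.FEMALE, Affection.AFFECTED),
        "B": PedigreeMember("B", "A", None, Sex.MALE, Affection.UNKNOWN),
    }
    issues = validate(Pedigree("F", members))
    assert issues and all(issue.startswith("warning") for issue in issues)


# ---------------------------------------------------------------------------
# mendelian_consistent


def _mendel_oracle(child, father, mother):
    """Enumerate the 2x2 gamete picks directly."""
    gametes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    return any(
        a + b == int(child) for a in gametes[int(father)] for b in gametes[int(mother)]
    )


def test_mendelian_examples():
    assert not mendelian_consistent(Call.HET, Call.HOM_REF, Call.HOM_REF)  # de novo
    assert mendelian_consistent(Call.HET, Call.HET, Call.HOM_REF)
    assert mendelian_consistent(Call.MISSING, Call.HOM_REF, Call.HOM_REF)


def test_mendelian_full_truth_table_matches_allele_enumeration():
    calls = [Call.HOM_REF, Call.HET, Call.HOM_ALT]
    for child, father, mother in itertools.product(calls, repeat=3):
        assert mendelian_consistent(child, father, mother) == _mendel_oracle(
            child, father, mother
        ), (child, father, mother)


# ---------------------------------------------------------------------------
# check_autosomal_dominant


def _ad_oracle(calls, pedigree, policy):
    """Direct enumeration of the stated pass rule, independent of the
    implementation's counting order."""
    count_fail = policy.missing_genotype_rule is MissingGenotypeRule.FAIL
    informative = 0
    n_anc = n_uc = 0
    homalt = False
    for member in pedigree.members.values():
        call = calls.get(member.individual_id, Call.MISSING)
        if member.affection is Affection.AFFECTED:
            if call is Call.MISSING:
                n_anc += count_fail
                continue
            informative += 1
            if call is Call.HOM_REF:
                n_anc += 1
            if call is Call.HOM_ALT and policy.require_het_in_affected:
                homalt = True
        elif member.affection is Affection.UNAFFECTED:
            if call is Call.MISSING:
                n_uc += count_fail
                continue
            if call in (Call.HET, Call.HOM_ALT):
                n_uc += 1
    if informative == 0:
        return False
    return (
        n_anc <= policy.max_affected_noncarriers
        and n_uc <= policy.max_unaffected_carriers
        and not homalt
    )


def test_perfect_segregation_passes(six_member_pedigree):
    calls = {"I-1": Call.HET, "I-2": Call.HOM_REF, "II-1": Call.HET,
             "II-2": Call.HOM_REF, "II-3": Call.HOM_REF, "III-1": Call.HET}
    result = check_autosomal_dominant(KEY, calls, six_member_pedigree)
    assert result.passed and result.reasons == []


def test_affected_noncarrier_fails(six_member_pedigree):
    calls = {"I-1": Call.HOM_REF, "II-1": Call.HET, "III-1": Call.HET}
    result = check_autosomal_dominant(KEY, calls, six_member_pedigree)
    assert not result.passed and AFFECTED_NONCARRIER in result.reasons


def test_unaffected_carrier_tolerance(six_member_pedigree):
    calls = {"I-1": Call.HET, "II-1": Call.HET, "III-1": Call.HET, "I-2": Call.HET}
    strict = check_autosomal_dominant(KEY, calls, six_member_pedigree)
    assert not strict.passed and UNAFFECTED_CARRIER in strict.reasons
    lenient = check_autosomal_dominant(
        KEY, calls, six_member_pedigree, SegregationPolicy(max_unaffected_carriers=1)
    )
    assert lenient.passed


def test_homalt_affected_fails_unless_allowed(six_member_pedigree):
    calls = {"I-1": Call.HOM_ALT, "II-1": Call.HET, "III-1": Call.HET}
    result = check_autosomal_dominant(KEY, calls, six_member_pedigree)
    assert not result.passed and AFFECTED_HOMALT in result.reasons
    relaxed = check_autosomal_dominant(
        KEY, calls, six_member_pedigree, SegregationPolicy(require_het_in_affected=False)
    )
    assert relaxed.passed


def test_no_informative_affected_genotype_fails(six_member_pedigree):
    calls = {"I-2": Call.HOM_REF, "II-3": Call.HOM_REF}
    result = check_autosomal_dominant(KEY, calls, six_member_pedigree)
    assert not result.passed and result.reasons == [NO_INFORMATIVE_GENOTYPES]


def test_calls_for_unknown_member_raise(six_member_pedigree):
    with pytest.raises(ConsistencyError):
        check_autosomal_dominant(KEY, {"GHOST": Call.HET}, six_member_pedigree)


def test_exhaustive_agreement_with_oracle_on_six_members(six_member_pedigree):
    """All 4^6 genotype assignments (incl. missing) under several policies."""
    ids = list(six_member_pedigree.members)
    policies = [
        SegregationPolicy(),
        SegregationPolicy(max_unaffected_carriers=1),
        SegregationPolicy(max_affected_noncarriers=1, require_het_in_affected=False),
        SegregationPolicy(missing_genotype_rule=MissingGenotypeRule.FAIL),
    ]
    all_calls = [Call.MISSING, Call.HOM_REF, Call.HET, Call.HOM_ALT]
    for combo in itertools.product(all_calls, repeat=len(ids)):
        calls = dict(zip(ids, combo))
        for policy in policies:
            got = check_autosomal_dominant(KEY, calls, six_member_pedigree, policy)
            assert got.passed == _ad_oracle(calls, six_member_pedigree, policy)


@given(
    genotypes=st.lists(st.sampled_from([Call.HOM_REF, Call.HET, Call.HOM_ALT]), min_size=6, max_size=6),
    tol_uc=st.integers(0, 3),
    tol_anc=st.integers(0, 3),
)
def test_monotone_in_tolerances(six_member_pedigree, genotypes, tol_uc, tol_anc):
    """Raising a tolerance never turns a pass into a fail."""
    calls = dict(zip(six_member_pedigree.members, genotypes))
    base = check_autosomal_dominant(
        KEY, calls, six_member_pedigree,
        SegregationPolicy(max_unaffected_carriers=tol_uc, max_affected_noncarriers=tol_anc),
    )
    wider = check_autosomal_dominant(
        KEY, calls, six_member_pedigree,
        SegregationPolicy(max_unaffected_carriers=tol_uc + 1, max_affected_noncarriers=tol_anc + 1),
    )
    assert wider.passed or not base.passed


@given(
    genotypes=st.lists(st.sampled_from(list(Call)), min_size=6, max_size=6),
    extra_call=st.sampled_from(list(Call)),
)
def test_unknown_phenotype_members_are_inert(six_member_pedigree, genotypes, extra_call):
    calls = dict(zip(six_member_pedigree.members, genotypes))
    base = check_autosomal_dominant(KEY, calls, six_member_pedigree)
    members = dict(six_member_pedigree.members)
    members["X"] = PedigreeMember("X", None, None, Sex.UNKNOWN, Affection.UNKNOWN)
    extended = Pedigree("F6", members)
    got = check_autosomal_dominant(KEY, {**calls, "X": extra_call}, extended)
    assert got.passed == base.passed


# ---------------------------------------------------------------------------
# filter_segregating


def _matrix(six_member_pedigree, rows):
    keys = [VariantKey("1", 100 + i, "A", "G") for i in range(len(rows))]
    return keys, GenotypeMatrix(keys, list(six_member_pedigree.members), np.array(rows, dtype=np.int8))


def test_filter_segregating_retains_only_segregating_variant(six_member_pedigree):
    # member order: I-1, I-2, II-1, II-2, II-3, III-1
    rows = [
        [1, 0, 1, 0, 0, 1],  # perfect segregation
        [0, 1, 0, 0, 1, 0],  # inverted: fails
        [1, 1, 1, 1, 1, 1],  # unaffected carriers: fails
    ]
    keys, matrix = _matrix(six_member_pedigree, rows)
    results = filter_segregating(keys, matrix, six_member_pedigree)
    assert [r.variant for r in results] == keys  # input order preserved
    assert [r.passed for r in results] == [True, False, False]


def test_filter_segregating_empty_and_sample_mismatch(six_member_pedigree):
    keys, matrix = _matrix(six_member_pedigree, [[1, 0, 1, 0, 0, 1]])
    assert filter_segregating([], matrix, six_member_pedigree) == []
    bad = GenotypeMatrix(keys, ["GHOST"] + list(six_member_pedigree.members)[1:], matrix.calls)
    with pytest.raises(ConsistencyError):
        filter_segregating(keys, bad, six_member_pedigree)


def test_filter_segregating_matches_oracle_on_random_families():
    rng = random.Random(7)
    for _ in range(25):
        n = 5
        members = {}
        for i in range(n):
            affection = rng.choice(list(Affection))
            members[f"M{i}"] = PedigreeMember(f"M{i}", None, None, Sex.UNKNOWN, affection)
        pedigree = Pedigree("R", members)
        keys = [VariantKey("1", 10 + j, "A", "G") for j in range(6)]
        rows = [[rng.choice([-1, 0, 1, 2]) for _ in range(n)] for _ in keys]
        matrix = GenotypeMatrix(keys, list(members), np.array(rows, dtype=np.int8))
        policy = SegregationPolicy(
            max_unaffected_carriers=rng.randint(0, 2),
            max_affected_noncarriers=rng.randint(0, 2),
            require_het_in_affected=rng.random() < 0.5,
        )
        results = filter_segregating(keys, matrix, pedigree, policy)
        for result in results:
            calls = matrix.calls_for(result.variant)
            assert result.passed == _ad_oracle(calls, pedigree, policy)
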