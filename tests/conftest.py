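import pytest
from hypothesis import HealthCheck, settings

from famvar.io_formats import AnnotatedVariant, Consequence, VariantKey
from famvar.pedigree import Affection, Pedigree, PedigreeMember, Sex
from famvar.simulate import fixture_candidates

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    # pedigree fixtures are immutable, so sharing them across examples is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_variant(
    gene="GENE",
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    consequence=Consequence.MISSENSE,
    maf=None,
    sift=None,
    polyphen2=None,
    cadd=None,
    gerp=None,
):
    return AnnotatedVariant(
        key=VariantKey(chrom, pos, ref, alt),
        gene=gene,
        consequence=consequence,
        cdna_change="c.X",
        maf_by_source={} if maf is None else {"gnomad": maf},
        sift=sift,
        polyphen2=polyphen2,
        cadd=cadd,
        gerp=gerp,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture(scope="session")
def table1_candidates():
    return fixture_candidates("table1")


@pytest.fixture(scope="session")
def table2_candidates():
    return fixture_candidates("table2")


@pytest.fixture(scope="session")
def pcdha5_candidates():
    return fixture_candidates("pcdha5")


def nuclear_trio(child_affection=Affection.AFFECTED):
    members = {
        "F": PedigreeMember("F", None, None, Sex.MALE, Affection.AFFECTED),
        "M": PedigreeMember("M", None, None, Sex.FEMALE, Affection.UNAFFECTED),
        "C": PedigreeMember("C", "F", "M", Sex.MALE, child_affection),
    }
    return Pedigree(family_id="T1", members=members)


@pytest.fixture
def six_member_pedigree():
    """Two founders, two children (one married in a spouse), one grandchild.

    Affection: founder father, child II-1 and grandchild III-1 affected;
    mother and spouse unaffected; child II-2 unknown phenotype.
    """
    members = {
        "I-1": PedigreeMember("I-1", None, None, Sex.MALE, Affection.AFFECTED),
        "I-2": PedigreeMember("I-2", None, None, Sex.FEMALE, Affection.UNAFFECTED),
        "II-1": PedigreeMember("II-1", "I-1", "I-2", Sex.MALE, Affection.AFFECTED),
        "II-2": PedigreeMember("II-2", "I-1", "I-2", Sex.FEMALE, Affection.UNKNOWN),
        "II-3": PedigreeMember("II-3", None, None, Sex.FEMALE, Affection.UNAFFECTED),
        "III-1": PedigreeMember("III-1", "II-1", "II-3", Sex.FEMALE, Affection.AFFECTED),
    }
    return Pedigree(family_id="F6", members=members)
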