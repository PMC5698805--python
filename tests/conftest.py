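import numpy as np
import pytest

from pedexome.pedigree import Affection, Individual, Pedigree, Sex


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_ind(iid, fam="F", fa=None, mo=None, sex=Sex.UNKNOWN,
             aff=Affection.UNKNOWN, sequenced=True):
    return Individual(
        iid, fam, father_id=fa, mother_id=mo, sex=sex, affection=aff, sequenced=sequenced
    )


@pytest.fixture
def trio():
    """Father, mother, one child."""
    return Pedigree(
        "F",
        [
            make_ind("dad", sex=Sex.MALE),
            make_ind("mum", sex=Sex.FEMALE),
            make_ind("kid", fa="dad", mo="mum"),
        ],
    )


@pytest.fixture
def three_gen():
    """Grandparents -> parent (+ spouse) -> two children."""
    return Pedigree(
        "F",
        [
            make_ind("gf", sex=Sex.MALE, aff=Affection.AFFECTED),
            make_ind("gm", sex=Sex.FEMALE, aff=Affection.UNAFFECTED),
            make_ind("p", fa="gf", mo="gm", sex=Sex.MALE, aff=Affection.AFFECTED),
            make_ind("sp", sex=Sex.FEMALE, aff=Affection.UNAFFECTED),
            make_ind("c1", fa="p", mo="sp", aff=Affection.AFFECTED),
            make_ind("c2", fa="p", mo="sp", aff=Affection.UNAFFECTED),
        ],
    )


@pytest.fixture
def informative_cross():
    """Phase-known fully informative cross: affected grandfather hom for
    marker allele 0, parent het, unaffected spouse hom allele 1, and ten
    affected children; with full penetrance and no phenocopies each child
    is one informative meiosis."""
    members = [
        make_ind("GF", sex=Sex.MALE, aff=Affection.AFFECTED),
        make_ind("GM", sex=Sex.FEMALE, aff=Affection.UNAFFECTED),
        make_ind("P", fa="GF", mo="GM", sex=Sex.MALE, aff=Affection.AFFECTED),
        make_ind("SP", sex=Sex.FEMALE, aff=Affection.UNAFFECTED),
    ] + [make_ind(f"K{i}", fa="P", mo="SP", aff=Affection.AFFECTED) for i in range(10)]
    ped = Pedigree("F", members)
    genotypes = {"GF": (0, 0), "GM": (1, 1), "P": (0, 1), "SP": (1, 1)}
    genotypes.update({f"K{i}": (0, 1) for i in range(10)})
    return ped, genotypes
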