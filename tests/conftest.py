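import numpy as np
import pytest

from pedagg import Cohort, Individual, kinship_matrix, reference_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic reconstruction of the 62-family survey cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def fixture_kinship(fixture_cohort):
    return kinship_matrix(fixture_cohort)


@pytest.fixture(scope="session")
def fixture_mask(fixture_cohort):
    return fixture_cohort.phenotype_mask("combined")


def nuclear_family(
    family_id="N1", n_children=2, prefix="", affected=(), father_kw=None
):
    """2 founder parents + n children, optionally affected."""
    f, m = f"{prefix}f", f"{prefix}m"
    inds = [
        Individual(id=f, family_id=family_id, sex="male",
                   phenotype="unaffected"),
        Individual(id=m, family_id=family_id, sex="female",
                   phenotype="unaffected"),
    ]
    for i in range(1, n_children + 1):
        inds.append(
            Individual(
                id=f"{prefix}c{i}", family_id=family_id, father_id=f,
                mother_id=m,
                phenotype=(
                    "myxedematous_severe" if f"{prefix}c{i}" in affected
                    or i in affected else "unaffected"
                ),
            )
        )
    return inds


@pytest.fixture
def toy_six_member_cohort():
    """One nuclear family (2 parents + 2 children) plus 2 unrelated founders."""
    inds = nuclear_family("N1", 2, affected=(1, 2))
    inds += [
        Individual(id="u1", family_id="N2", phenotype="unaffected"),
        Individual(id="u2", family_id="N2", phenotype="unaffected"),
    ]
    return Cohort(inds)


@pytest.fixture
def three_generation_cohort():
    """Grandparent couple -> one parent (married-in spouse) -> two children."""
    inds = [
        Individual(id="gf", family_id="G", sex="male", phenotype="unaffected"),
        Individual(id="gm", family_id="G", sex="female",
                   phenotype="unaffected"),
        Individual(id="p1", family_id="G", father_id="gf", mother_id="gm",
                   sex="male", phenotype="unaffected"),
        Individual(id="sp", family_id="G", sex="female",
                   phenotype="unaffected"),
        Individual(id="k1", family_id="G", father_id="p1", mother_id="sp",
                   phenotype="unaffected"),
        Individual(id="k2", family_id="G", father_id="p1", mother_id="sp",
                   phenotype="unaffected"),
    ]
    return Cohort(inds)
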