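"""Shared pedigree fixtures, built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from pedliab.pedigree import FamilyGraph, Individual


def _ind(iid, fam, fa, mo, sex, affected=False, proband=False, yob=1940, age=None):
    return Individual(
        individual_id=iid, family_id=fam, father_id=fa, mother_id=mo, sex=sex,
        affected=affected, is_proband=proband, year_of_birth=yob,
        age_at_enrollment=age if age is not None else max(1995 - yob, 0),
    )


@pytest.fixture
def trio():
    """Father, mother, affected proband child."""
    return FamilyGraph("T", [
        _ind("f", "T", None, None, "male", yob=1920),
        _ind("m", "T", None, None, "female", yob=1922),
        _ind("c", "T", "f", "m", "female", affected=True, proband=True, yob=1950),
    ])


@pytest.fixture
def nuclear5():
    """Two parents, three offspring."""
    kids = [
        _ind(f"k{i}", "N", "f", "m", "male" if i % 2 else "female", yob=1948 + i)
        for i in range(3)
    ]
    return FamilyGraph("N", [
        _ind("f", "N", None, None, "male", yob=1920),
        _ind("m", "N", None, None, "female", yob=1921),
        *kids,
    ])


@pytest.fixture
def cousins():
    """Three generations: grandparents, two sib parents with spouses, two
    first-cousin grandchildren."""
    return FamilyGraph("C", [
        _ind("gf", "C", None, None, "male", yob=1895),
        _ind("gm", "C", None, None, "female", yob=1897),
        _ind("a", "C", "gf", "gm", "male", yob=1920),
        _ind("b", "C", "gf", "gm", "female", yob=1922),
        _ind("sa", "C", None, None, "female", yob=1921),
        _ind("sb", "C", None, None, "male", yob=1923),
        _ind("ca", "C", "a", "sa", "male", affected=True, proband=True, yob=1950),
        _ind("cb", "C", "sb", "b", "female", yob=1952),
    ])


@pytest.fixture
def random_pedigrees():
    """Small random pedigrees (<= 12 members) from the generator."""
    from pedliab.simulate import PedigreeShape, generate_pedigree

    rng = np.random.default_rng(2024)
    shape = PedigreeShape(generations=(2, 3), mean_offspring=1.6, p_marry=0.6)
    fams = []
    i = 0
    while len(fams) < 6 and i < 500:
        i += 1
        fam = generate_pedigree(shape, rng, family_id=f"R{i}")
        if 3 <= len(fam) <= 12:
            fams.append(fam)
    return fams


def make_ind(*args, **kwargs):
    return _ind(*args, **kwargs)
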