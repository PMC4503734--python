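import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from babblercalls.core_io import Individual, Pedigree, ValidationError
from babblercalls import pedigree as ped_mod
from babblercalls.pedigree import (
    NeighbourProfile,
    is_related_group,
    profile_neighbour,
    relatedness,
    relatedness_matrix,
)

REF = dt.date(2011, 1, 15)
ADULT = dt.date(2008, 1, 1)
JUVENILE = dt.date(2010, 12, 1)


def kinship_oracle(ped: Pedigree, i: str, j: str) -> float:
    """Independent recursive coancestry oracle; r = 2 * kinship for i != j."""
    order = {ind: k for k, ind in enumerate(ped.topological_order)}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        if a == b:
            da, sa = ped.parents(a)
            return 0.5 * (1.0 + f(da, sa))
        # recurse on the later-born (descendant-side) individual
        if order[a] < order[b]:
            a, b = b, a
        da, sa = ped.parents(a)
        return 0.5 * (f(da, b) + f(sa, b))

    # off-diagonal: numerator relationship = 2 * kinship;
    # diagonal: 1 + F where the inbreeding coefficient F = kinship(dam, sire)
    return 2.0 * f(i, j) if i != j else 1.0 + f(*ped.parents(i))


class TestRelatedness:
    def test_textbook_relationships(self):
        ped = Pedigree(
            {
                "F1": (None, None),
                "M1": (None, None),
                "M2": (None, None),
                "kid": ("F1", "M1"),
                "sib": ("F1", "M1"),
                "half": ("F1", "M2"),
                "grandkid": ("kid", "M2"),
            }
        )
        A = relatedness_matrix(ped)
        assert relatedness(A, "kid", "F1") == pytest.approx(0.5)  # parent-offspring
        assert relatedness(A, "kid", "sib") == pytest.approx(0.5)  # full siblings
        assert relatedness(A, "kid", "half") == pytest.approx(0.25)  # half siblings
        assert relatedness(A, "grandkid", "F1") == pytest.approx(0.25)  # grandparent
        assert relatedness(A, "F1", "M1") == 0.0  # founders
        assert relatedness(A, "kid", "kid") == pytest.approx(1.0)

    def test_unknown_individuals_are_founders(self):
        A = relatedness_matrix(Pedigree({"X": (None, None)}))
        assert relatedness(A, "X", "nobody") == 0.0
        assert relatedness(A, "nobody", "nobody") == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matrix_matches_recursive_kinship_oracle(self, seed):
        """Random 4-generation pedigrees: tabular matrix == recursion."""
        rng = np.random.default_rng(seed)
        parents = {}
        generations = [[f"g0_{k}" for k in range(4)]]
        for ind in generations[0]:
            parents[ind] = (None, None)
        for g in range(1, 4):
            pool = [i for gen in generations for i in gen]
            gen = []
            for k in range(rng.integers(2, 5)):
                dam, sire = rng.choice(len(pool), size=2, replace=False)
                name = f"g{g}_{k}"
                parents[name] = (pool[dam], pool[sire])
                gen.append(name)
            generations.append(gen)
        ped = Pedigree(parents)
        A = relatedness_matrix(ped)
        ids = ped.ids
        for i in ids:
            for j in ids:
                assert A.at[i, j] == pytest.approx(kinship_oracle(ped, i, j), abs=1e-12)


def _group(*members):
    return list(members)


def _ind(id, sex, hatch, group="N", rank="subordinate"):
    return Individual(id, sex, hatch, group, rank)


class TestGroupClassification:
    @pytest.fixture()
    def family(self):
        ped = Pedigree(
            {
                "mum": (None, None),
                "dad": (None, None),
                "caller": ("mum", "dad"),
                "halfsib": ("mum", None),
                "stranger": (None, None),
            }
        )
        return relatedness_matrix(ped)

    def test_related_via_dominant_mother(self, family):
        group = _group(
            _ind("mum", "female", ADULT, rank="dominant"),
            _ind("imm", "male", ADULT, rank="dominant"),
        )
        assert is_related_group("caller", group, family) is True

    def test_unrelated_founders(self, family):
        group = _group(
            _ind("stranger", "female", ADULT, rank="dominant"),
            _ind("imm", "male", ADULT, rank="dominant"),
        )
        assert is_related_group("caller", group, family) is False

    def test_threshold_is_inclusive_at_quarter(self, family):
        group = _group(
            _ind("halfsib", "female", ADULT, rank="dominant"),
            _ind("imm", "male", ADULT, rank="dominant"),
        )
        assert relatedness(family, "caller", "halfsib") == pytest.approx(0.25)
        assert is_related_group("caller", group, family) is True

    def test_no_dominants_is_an_error(self, family):
        with pytest.raises(ValidationError, match="N"):
            is_related_group("caller", [_ind("x", "male", ADULT)], family)


class TestNeighbourProfile:
    @pytest.fixture()
    def matrix(self):
        ped = Pedigree(
            {
                "mum": (None, None),
                "dad": (None, None),
                "caller": ("mum", "dad"),
                "sib1": ("mum", "dad"),
                "sib2": ("mum", "dad"),
                "rel_f": ("mum", "dad"),
            }
        )
        return relatedness_matrix(ped)

    def test_empty_group(self, matrix):
        caller = _ind("caller", "male", ADULT, group="F")
        p = profile_neighbour(caller, [], matrix, REF)
        assert (p.n_adults, p.n_potential_partners, p.n_same_sex_unrelated_adults) == (0, 0, 0)

    def test_all_full_siblings_no_partners(self, matrix):
        caller = _ind("caller", "male", ADULT, group="F")
        group = _group(
            _ind("sib1", "female", ADULT, rank="dominant"),
            _ind("sib2", "male", ADULT, rank="dominant"),
        )
        p = profile_neighbour(caller, group, matrix, REF)
        assert p.related is True
        assert p.n_potential_partners == 0

    def test_mixed_group_counts(self, matrix):
        """2 unrelated adult F + 1 related adult F + 1 unrelated juvenile F +
        1 unrelated adult M, male caller -> 2 potential partners."""
        caller = _ind("caller", "male", ADULT, group="F")
        group = _group(
            _ind("uf1", "female", ADULT, rank="dominant"),
            _ind("um1", "male", ADULT, rank="dominant"),
            _ind("uf2", "female", ADULT),
            _ind("rel_f", "female", ADULT),
            _ind("juv_f", "female", JUVENILE),
        )
        p = profile_neighbour(caller, group, matrix, REF)
        assert p.n_adults == 4
        assert p.n_potential_partners == 2
        assert p.n_same_sex_unrelated_adults == 1
        assert p.n_potential_partners + p.n_same_sex_unrelated_adults <= p.n_adults

    def test_partner_count_monotone_in_unrelated_adults(self, matrix):
        caller = _ind("caller", "male", ADULT, group="F")
        group = [
            _ind("uf1", "female", ADULT, rank="dominant"),
            _ind("um1", "male", ADULT, rank="dominant"),
        ]
        before = profile_neighbour(caller, group, matrix, REF).n_potential_partners
        group.append(_ind("uf2", "female", ADULT))
        after = profile_neighbour(caller, group, matrix, REF).n_potential_partners
        assert after == before + 1

    def test_unknown_sex_caller_rejected(self, matrix):
        caller = _ind("caller", "unknown", ADULT, group="F")
        with pytest.raises(ValidationError, match="unknown sex"):
            profile_neighbour(caller, [], matrix, REF)

    def test_adult_threshold_inclusive_at_365_days(self, matrix):
        caller = _ind("caller", "male", ADULT, group="F")
        boundary = REF - dt.timedelta(days=365)
        group = _group(
            _ind("uf1", "female", boundary, rank="dominant"),
            _ind("um1", "male", ADULT, rank="dominant"),
        )
        assert profile_neighbour(caller, group, matrix, REF).n_potential_partners == 1
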