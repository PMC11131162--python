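"""Derived kinship relations: worked examples, oracles and invariants."""

import numpy as np
import pytest

from kinqc import inference as inf
from kinqc.errors import InconsistentFactBaseError, MissingPersonError
from kinqc.model import FEMALE, MALE, TimePoint
from kinqc.simulate import generate_clean

from .conftest import closure_oracle, make_factbase


class TestParenthood:
    def test_parent_link_is_directional(self):
        fb = make_factbase([("amy", FEMALE), ("bob", MALE)], links=[("amy", "bob")])
        assert inf.natural_parent_of(fb, "amy", "bob")
        assert not inf.natural_parent_of(fb, "bob", "amy")
        assert not inf.natural_parent_of(fb, "amy", "amy")

    def test_unregistered_person_raises(self):
        fb = make_factbase([("amy", FEMALE)])
        with pytest.raises(MissingPersonError):
            inf.natural_parent_of(fb, "amy", "ghost")

    def test_sexed_parenthood(self):
        fb = make_factbase(
            [("p", None), ("q", (MALE, FEMALE)), ("c", None), ("d", None)],
            links=[("p", "c"), ("q", "d")],
        )
        # no sex quality: neither father nor mother
        assert not inf.natural_father_of(fb, "p", "c")
        assert not inf.natural_mother_of(fb, "p", "c")
        # both sex qualities: the definitions make q both father and mother
        assert inf.natural_father_of(fb, "q", "d")
        assert inf.natural_mother_of(fb, "q", "d")


class TestAncestry:
    def test_chain_is_transitive_and_irreflexive(self):
        fb = make_factbase(
            [("a", None), ("b", None), ("c", None)], links=[("a", "b"), ("b", "c")]
        )
        assert inf.natural_ancestor_of(fb, "a", "c")
        assert not inf.natural_ancestor_of(fb, "c", "a")
        assert all(not inf.natural_ancestor_of(fb, x, x) for x in fb.persons)

    def test_maternal_grandfather_is_ancestor(self):
        fb = make_factbase(
            [("grandfather", MALE), ("nancy", FEMALE), ("lincoln", MALE)],
            links=[("grandfather", "nancy"), ("nancy", "lincoln")],
        )
        assert inf.natural_ancestor_of(fb, "grandfather", "lincoln")
        assert inf.natural_maternal_grandparent_of(fb, "grandfather", "lincoln")

    def test_cycle_raises(self):
        fb = make_factbase([("a", None), ("b", None)], links=[("a", "b"), ("b", "a")])
        with pytest.raises(InconsistentFactBaseError):
            inf.natural_ancestor_of(fb, "a", "b")

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_matrix_closure_oracle(self, seed):
        """Random DAGs up to 50 persons: traversal equals boolean matrix
        repeated squaring."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        ids = [f"p{i}" for i in range(n)]
        links = [
            (ids[a], ids[b])
            for a, b in rng.integers(0, n, size=(3 * n, 2))
            if a < b  # topological order guarantees a DAG
        ]
        fb = make_factbase([(i, None) for i in ids], links=list(set(links)))
        assert inf.ancestor_closure(fb) == closure_oracle(fb)


class TestSiblings:
    def test_half_siblings_count_by_default_but_not_in_full_mode(self):
        fb = make_factbase(
            [("m", FEMALE), ("f1", MALE), ("f2", MALE), ("x", None), ("y", None)],
            links=[("m", "x"), ("m", "y"), ("f1", "x"), ("f2", "y")],
        )
        assert inf.natural_sibling_of(fb, "x", "y")
        assert not inf.natural_sibling_of(fb, "x", "y", full_siblings_only=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_irreflexive_on_generated_pedigrees(self, seed):
        fb = generate_clean(seed, generations=3, founders=4)
        people = sorted(fb.persons)
        for x in people:
            assert not inf.natural_sibling_of(fb, x, x)
            for y in people:
                assert inf.natural_sibling_of(fb, x, y) == inf.natural_sibling_of(fb, y, x)


class TestGrandparents:
    def test_linking_parent_sex_decides_maternal_paternal(self):
        # A is B's father; B is C's mother: A is a MATERNAL grandparent of C
        fb = make_factbase(
            [("a", MALE), ("b", FEMALE), ("c", None)], links=[("a", "b"), ("b", "c")]
        )
        assert inf.natural_grandparent_of(fb, "a", "c")
        assert inf.natural_maternal_grandparent_of(fb, "a", "c")
        assert not inf.natural_paternal_grandparent_of(fb, "a", "c")

    def test_sexless_linking_parent_gives_base_relation_only(self):
        fb = make_factbase(
            [("a", MALE), ("b", None), ("c", None)], links=[("a", "b"), ("b", "c")]
        )
        assert inf.natural_grandparent_of(fb, "a", "c")
        assert not inf.natural_maternal_grandparent_of(fb, "a", "c")
        assert not inf.natural_paternal_grandparent_of(fb, "a", "c")


def aunt_uncle_fb(*, uncle_birth=1950, mother_birth=1955):
    return make_factbase(
        [
            ("g1", MALE, 1920),
            ("g2", FEMALE, 1922),
            ("uncle", MALE, uncle_birth),
            ("mother", FEMALE, mother_birth),
            ("kid", None, 1980),
        ],
        links=[
            ("g1", "uncle"), ("g2", "uncle"),
            ("g1", "mother"), ("g2", "mother"),
            ("mother", "kid"),
        ],
    )


class TestAuntsUncles:
    def test_older_uncle_via_linking_parent_birth(self):
        fb = aunt_uncle_fb(uncle_birth=1950, mother_birth=1955)
        assert inf.natural_uncle_of(fb, "uncle", "kid")
        assert inf.natural_older_uncle_of(fb, "uncle", "kid")
        assert not inf.natural_younger_uncle_of(fb, "uncle", "kid")

    def test_missing_birth_leaves_age_order_indeterminate(self):
        fb = aunt_uncle_fb(uncle_birth=None, mother_birth=1955)
        assert inf.natural_uncle_of(fb, "uncle", "kid")
        assert not inf.natural_older_uncle_of(fb, "uncle", "kid")
        assert not inf.natural_younger_uncle_of(fb, "uncle", "kid")

    def test_existential_over_linking_parents(self):
        """With two linking parents giving opposite age orders, both the
        older and the younger relation hold (existential reading)."""
        fb = make_factbase(
            [
                ("g", FEMALE, 1900),
                ("aunt", FEMALE, 1950),
                ("p1", FEMALE, 1945),
                ("p2", MALE, 1955),
                ("kid", None, 1980),
            ],
            links=[
                ("g", "aunt"), ("g", "p1"), ("g", "p2"),
                ("p1", "kid"), ("p2", "kid"),
            ],
        )
        assert inf.natural_older_aunt_of(fb, "aunt", "kid")  # older than p2
        assert inf.natural_younger_aunt_of(fb, "aunt", "kid")  # younger than p1

    def test_niece_nephew_are_sexed_converse_style(self):
        fb = make_factbase(
            [
                ("g", FEMALE), ("uncle", MALE), ("mother", FEMALE),
                ("niece", FEMALE), ("nobody", None),
            ],
            links=[("g", "uncle"), ("g", "mother"), ("mother", "niece"), ("mother", "nobody")],
        )
        assert inf.natural_niece_of(fb, "niece", "uncle")
        assert not inf.natural_nephew_of(fb, "niece", "uncle")
        assert not inf.natural_niece_of(fb, "nobody", "uncle")  # sexless

    @pytest.mark.parametrize("seed", range(5))
    def test_age_variants_within_base_and_disjoint(self, seed):
        """older ∪ younger ⊆ uncle/aunt; disjoint when births are present
        and distinct (the generator guarantees distinct sibship births)."""
        fb = generate_clean(seed, generations=3, founders=4)
        for x in fb.persons:
            for y in fb.persons:
                if x == y:
                    continue
                for base, older, younger in (
                    (inf.natural_uncle_of, inf.natural_older_uncle_of, inf.natural_younger_uncle_of),
                    (inf.natural_aunt_of, inf.natural_older_aunt_of, inf.natural_younger_aunt_of),
                ):
                    o, yng = older(fb, x, y), younger(fb, x, y)
                    if o or yng:
                        assert base(fb, x, y)
                    assert not (o and yng)


class TestCousins:
    def test_children_of_two_sisters_are_cousins(self):
        fb = make_factbase(
            [("g", FEMALE), ("s1", FEMALE), ("s2", FEMALE), ("c1", None), ("c2", None)],
            links=[("g", "s1"), ("g", "s2"), ("s1", "c1"), ("s2", "c2")],
        )
        assert inf.natural_first_cousin_of(fb, "c1", "c2")
        assert inf.natural_first_cousin_of(fb, "c2", "c1")

    def test_double_first_cousins_hold_once(self):
        """Both parent pairs are sibling pairs: the relation holds (as one
        boolean instance, not two)."""
        fb = make_factbase(
            [
                ("ga", MALE), ("gb", FEMALE), ("gc", MALE), ("gd", FEMALE),
                ("b1", MALE), ("b2", MALE), ("s1", FEMALE), ("s2", FEMALE),
                ("c1", None), ("c2", None),
            ],
            links=[
                ("ga", "b1"), ("gb", "b1"), ("ga", "b2"), ("gb", "b2"),
                ("gc", "s1"), ("gd", "s1"), ("gc", "s2"), ("gd", "s2"),
                ("b1", "c1"), ("s1", "c1"), ("b2", "c2"), ("s2", "c2"),
            ],
        )
        assert inf.natural_first_cousin_of(fb, "c1", "c2")
        instances = [
            r for r in inf.infer_all(fb)
            if r.relation == "natural-first-cousin-of" and r.args == ("c1", "c2")
        ]
        assert len(instances) == 1

    def test_sibling_pair_excluded_even_with_sibling_parents(self):
        fb = make_factbase(
            [("g", FEMALE), ("p1", MALE), ("p2", FEMALE), ("x", None), ("y", None)],
            links=[("g", "p1"), ("g", "p2"), ("p1", "x"), ("p2", "x"), ("p1", "y"), ("p2", "y")],
        )
        # x and y share both parents -> siblings, not first cousins
        assert inf.natural_sibling_of(fb, "x", "y")
        assert not inf.natural_first_cousin_of(fb, "x", "y")


class TestSpousehood:
    def test_time_indexed_and_irreflexive(self):
        fb = make_factbase(
            [("f", MALE), ("s", FEMALE)], bonds=[("m1", "f", "s", 2000, None)]
        )
        assert inf.has_spouse_at(fb, "f", "s", TimePoint(2010))
        assert inf.has_spouse_at(fb, "s", "f", TimePoint(2010))
        assert not inf.has_spouse_at(fb, "f", "s", TimePoint(1999))
        assert not inf.has_spouse_at(fb, "f", "f", TimePoint(2010))
        assert inf.has_spouse_ever(fb, "f", "s")


class TestInferAll:
    def test_nuclear_family_enumeration(self, nuclear):
        got = {(r.relation, *r.args) for r in inf.infer_all(nuclear)}
        expected = set()
        for rel in ("has-natural-child", "natural-parent-of", "natural-ancestor-of"):
            expected |= {(rel, p, c) for p in "fm" for c in "ab"}
        expected |= {("natural-father-of", "f", c) for c in "ab"}
        expected |= {("natural-mother-of", "m", c) for c in "ab"}
        expected |= {("natural-sibling-of", "a", "b"), ("natural-sibling-of", "b", "a")}
        expected |= {("has-spouse", "f", "m"), ("has-spouse", "m", "f")}
        assert got == expected

    def test_empty_factbase_yields_nothing(self):
        from kinqc.model import FactBase

        assert inf.infer_all(FactBase()) == []

    def test_output_is_sorted_and_deterministic(self, nuclear):
        out1 = inf.infer_all(nuclear)
        out2 = inf.infer_all(nuclear)
        assert out1 == out2 == sorted(out1, key=lambda r: (r.relation, r.args))

    @pytest.mark.parametrize("seed", range(3))
    def test_support_facts_rederive_each_instance(self, seed):
        """Sound support: every derived instance's support atoms are ground
        facts of the base, and the instance follows from them alone."""
        from kinqc.rules import ground_facts, kinship_rules
        from kinqc.engine import fixpoint

        fb = generate_clean(seed, generations=3, founders=4)
        ground = ground_facts(fb)
        base_preds = {"has-natural-child", "sex-quality", "marriage-bond", "birth"}
        for inst in inf.infer_all(fb):
            assert inst.support, inst
            for atom in inst.support:
                assert atom[0] in base_preds
                if atom[0] in ("has-natural-child", "sex-quality"):
                    assert atom in ground
        # spot-check full re-derivation for the support of sibling instances
        sib = [r for r in inf.infer_all(fb) if r.relation == "natural-sibling-of"][:10]
        for inst in sib:
            mini = set(inst.support) | {("distinct", *inst.args), ("distinct", *inst.args[::-1])}
            fp = fixpoint(kinship_rules(), mini)
            assert ("natural-sibling-of", *inst.args) in fp

    @pytest.mark.parametrize("seed", range(3))
    def test_irreflexivity_of_all_relations(self, seed):
        fb = generate_clean(seed, generations=3, founders=4)
        for r in inf.infer_all(fb):
            if len(r.args) == 2:
                assert r.args[0] != r.args[1], r

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_of_sibling_cousin_spouse(self, seed):
        fb = generate_clean(seed, generations=3, founders=4)
        got = {(r.relation, *r.args) for r in inf.infer_all(fb)}
        for rel in ("natural-sibling-of", "natural-first-cousin-of", "has-spouse"):
            for item in got:
                if item[0] == rel:
                    assert (rel, item[2], item[1]) in got
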