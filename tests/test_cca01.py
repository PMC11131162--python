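"""The nine family-history categories and claim reconciliation."""

from io import StringIO

import pytest

from kinqc.cca01 import (
    CONFIRMED,
    CONTRADICTED,
    INDETERMINATE_AGE,
    UNVERIFIABLE,
    Cca01Category,
    FamilyHistoryRecord,
    classify,
    findings_to_tsv,
    load_records,
    reconcile,
)
from kinqc.inference import infer_all
from kinqc.model import FEMALE, MALE

from .conftest import make_factbase


class TestVocabulary:
    def test_exactly_nine_categories_with_bijective_labels(self):
        assert len(Cca01Category) == 9
        assert [int(c) for c in Cca01Category] == list(range(1, 10))
        labels = {c.label for c in Cca01Category}
        assert len(labels) == 9
        assert Cca01Category(9).label == "spouse"

    def test_subject_relative_must_differ(self):
        with pytest.raises(ValueError):
            FamilyHistoryRecord("a", "a", Cca01Category.PARENT)


@pytest.fixture
def extended():
    """Grandparents, an older uncle, parents, two children, a nephew and a
    spouse — one of each category reachable from subject 'kid'."""
    return make_factbase(
        persons=[
            ("gpf", MALE, 1900), ("gmf", FEMALE, 1902),   # paternal grandparents
            ("gpm", MALE, 1904), ("gmm", FEMALE, 1906),   # maternal grandparents
            ("dad", MALE, 1930), ("mom", FEMALE, 1935),
            ("unc", MALE, 1932),                            # mom's older brother
            ("kid", FEMALE, 1960), ("sib", MALE, 1962),
            ("son", MALE, 1985),
            ("nep", MALE, 1988),                            # sib's son
            ("hub", MALE, 1958),
        ],
        links=[
            ("gpf", "dad"), ("gmf", "dad"),
            ("gpm", "mom"), ("gmm", "mom"), ("gpm", "unc"), ("gmm", "unc"),
            ("dad", "kid"), ("mom", "kid"), ("dad", "sib"), ("mom", "sib"),
            ("kid", "son"), ("sib", "nep"),
        ],
        bonds=[("m1", "kid", "hub", 1980, None)],
    )


class TestClassify:
    @pytest.mark.parametrize(
        "relative,expected",
        [
            ("gpf", {Cca01Category.PATERNAL_GRANDPARENT}),
            ("gpm", {Cca01Category.MATERNAL_GRANDPARENT}),
            ("unc", {Cca01Category.OLDER_AUNT_OR_UNCLE}),
            ("mom", {Cca01Category.PARENT}),
            ("son", {Cca01Category.CHILD}),
            ("sib", {Cca01Category.SIBLING}),
            ("nep", {Cca01Category.NEPHEW_OR_NIECE}),
            ("hub", {Cca01Category.SPOUSE}),
        ],
    )
    def test_one_category_per_ordinary_relative(self, extended, relative, expected):
        assert classify(extended, "kid", relative) == expected

    def test_younger_uncle(self, extended):
        # unc (1932) is OLDER than mom (1935); from sib's son's view unchanged,
        # but a younger aunt case: swap birth order via kid's view of dad's side
        fb = make_factbase(
            [("g1", MALE, 1900), ("g2", FEMALE, 1901),
             ("mom", FEMALE, 1930), ("aunt", FEMALE, 1934), ("kid", None, 1960)],
            links=[("g1", "mom"), ("g2", "mom"), ("g1", "aunt"), ("g2", "aunt"),
                   ("mom", "kid")],
        )
        assert classify(fb, "kid", "aunt") == {Cca01Category.YOUNGER_AUNT_OR_UNCLE}

    def test_chinatown_multi_membership(self, chinatown):
        got = classify(chinatown, "katherine", "noah")
        assert got == {Cca01Category.PARENT, Cca01Category.MATERNAL_GRANDPARENT}

    def test_unrelated_pair_gets_empty_set(self, extended):
        assert classify(extended, "kid", "gmf") == {Cca01Category.PATERNAL_GRANDPARENT}
        assert classify(extended, "hub", "unc") == set()

    def test_consistent_with_materialized_relations(self, extended):
        """classify(subject, relative) agrees with infer_all's instances for
        each category's defining relation."""
        defining = {
            Cca01Category.PATERNAL_GRANDPARENT: "natural-paternal-grandparent-of",
            Cca01Category.MATERNAL_GRANDPARENT: "natural-maternal-grandparent-of",
            Cca01Category.PARENT: "natural-parent-of",
            Cca01Category.SIBLING: "natural-sibling-of",
            Cca01Category.SPOUSE: "has-spouse",
        }
        materialized = {(r.relation, *r.args) for r in infer_all(extended)}
        people = sorted(extended.persons)
        for subject in people:
            for relative in people:
                if subject == relative:
                    continue
                got = classify(extended, subject, relative)
                for category, relation in defining.items():
                    assert (category in got) == ((relation, relative, subject) in materialized)


class TestReconcile:
    def test_half_sibling_confirms_sibling_under_default_policy(self):
        fb = make_factbase(
            [("m", FEMALE), ("f1", MALE), ("f2", MALE), ("x", None), ("y", None)],
            links=[("m", "x"), ("m", "y"), ("f1", "x"), ("f2", "y")],
        )
        rec = FamilyHistoryRecord("x", "y", Cca01Category.SIBLING)
        assert reconcile(fb, [rec])[0].status == CONFIRMED
        assert reconcile(fb, [rec], full_siblings_only=True)[0].status == UNVERIFIABLE

    def test_unrecorded_spouse_is_unverifiable(self, extended):
        rec = FamilyHistoryRecord("kid", "gpf", Cca01Category.SPOUSE)
        finding = reconcile(extended, [rec])[0]
        assert finding.status == CONTRADICTED  # grandparent path exists
        rec2 = FamilyHistoryRecord("hub", "unc", Cca01Category.SPOUSE)
        assert reconcile(extended, [rec2])[0].status == UNVERIFIABLE

    def test_missing_birth_gives_indeterminate_age(self):
        fb = make_factbase(
            [("g", FEMALE), ("unc", MALE), ("mom", FEMALE, 1950), ("kid", None)],
            links=[("g", "unc"), ("g", "mom"), ("mom", "kid")],
        )
        rec = FamilyHistoryRecord("kid", "unc", Cca01Category.OLDER_AUNT_OR_UNCLE)
        finding = reconcile(fb, [rec])[0]
        assert finding.status == INDETERMINATE_AGE

    def test_records_load_and_findings_render(self, extended):
        records = load_records(
            StringIO(
                "subject_id\trelative_id\tcategory_code\tdiagnosis\n"
                "kid\tmom\t5\t1\n"
                "kid\tunc\t4\t1\n"
            )
        )
        findings = reconcile(extended, records)
        assert [f.status for f in findings] == [CONFIRMED, CONTRADICTED]
        tsv = findings_to_tsv(findings)
        assert "confirmed" in tsv and "contradicted" in tsv
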