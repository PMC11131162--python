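"""Fact-base loading, integrity checks, time semantics and round-trips."""

from io import StringIO

import pytest

from kinqc.errors import MissingPersonError, ParseError, TimeScaleError
from kinqc.model import (
    FEMALE,
    MALE,
    FactBase,
    Person,
    TimeInterval,
    TimePoint,
    exists_at,
    factbase_from_dict,
    factbase_to_dict,
    load_pedigree,
    parse_timepoint,
    validate,
    write_factbase,
)
from kinqc.simulate import generate_clean

from .conftest import closure_oracle, make_factbase

PED_HEADER = "person_id\tfather_id\tmother_id\tsex\tbirth\tdeath\n"


def ped(*rows: str) -> StringIO:
    return StringIO(PED_HEADER + "".join(r + "\n" for r in rows))


class TestLoadPedigree:
    def test_row_maps_to_links_and_sex(self):
        fb = load_pedigree(
            ped("N\t0\t0\t1\t.\t.", "E\t0\t0\t2\t.\t.", "K\tN\tE\t2\t.\t.")
        )
        assert fb.parents_of("K") == {"N", "E"}
        assert fb.sexes_of("K") == {FEMALE}
        assert fb.sexes_of("N") == {MALE}

    def test_empty_table_gives_empty_factbase(self):
        fb = load_pedigree(ped())
        assert not fb.persons and not fb.parent_links

    def test_unknown_parent_id_raises(self):
        with pytest.raises(MissingPersonError, match="GHOST"):
            load_pedigree(ped("K\tGHOST\t0\t2\t.\t."))

    def test_malformed_sex_code_reports_row(self):
        with pytest.raises(ParseError, match="row 3"):
            load_pedigree(ped("A\t0\t0\t1\t.\t.", "B\t0\t0\t9\t.\t."))

    def test_unions_open_end_sentinel(self):
        fb = load_pedigree(
            ped("A\t0\t0\t1\t1960\t.", "B\t0\t0\t2\t1962\t."),
            StringIO("bond_id\tpartner_a\tpartner_b\tstart\tend\nm1\tA\tB\t1984\t.\n"),
        )
        bond = fb.marriage_bonds["m1"]
        assert bond.interval.end is None
        assert bond.interval.contains(TimePoint(99999))


class TestValidate:
    def test_self_parent(self):
        fb = make_factbase([("A", None)], links=[("A", "A")])
        assert [v.kind for v in validate(fb)] == ["self-parent"]

    def test_two_cycle_is_parental_cycle(self):
        fb = make_factbase([("A", None), ("B", None)], links=[("A", "B"), ("B", "A")])
        [v] = validate(fb)
        assert v.kind == "parental-cycle" and set(v.participants) == {"A", "B"}

    def test_self_spouse(self):
        fb = make_factbase([("A", None)], bonds=[("m1", "A", "A", 2000)])
        assert [v.kind for v in validate(fb)] == ["self-spouse"]

    def test_two_male_parents_flagged(self):
        fb = make_factbase(
            [("A", MALE), ("B", MALE), ("C", None)], links=[("A", "C"), ("B", "C")]
        )
        [v] = validate(fb)
        assert v.kind == "duplicate-sexed-parent" and set(v.participants) == {"A", "B", "C"}

    def test_bond_before_birth_flagged_only_when_known(self):
        fb = make_factbase(
            [("A", MALE, 1990), ("B", FEMALE, None)], bonds=[("m1", "A", "B", 1980)]
        )
        assert [v.kind for v in validate(fb)] == ["bond-outside-lifespan"]

    @pytest.mark.parametrize("seed", range(5))
    def test_clean_generator_is_consistent(self, seed):
        assert validate(generate_clean(seed)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_cycle_detection_matches_reachability_oracle(self, seed):
        """Acyclicity violation iff some person reaches itself in the
        brute-force transitive closure."""
        import numpy as np

        rng = np.random.default_rng(seed)
        fb = FactBase()
        n = int(rng.integers(5, 50))
        for i in range(n):
            fb.add_person(Person(f"p{i}"))
        from kinqc.model import ParentLink

        for _ in range(int(rng.integers(n, 3 * n))):
            a, b = rng.integers(0, n, size=2)
            if a != b:
                fb.add_parent_link(ParentLink(f"p{a}", f"p{b}"))
        has_cycle_oracle = any((p, p) in closure_oracle(fb) for p in fb.persons)
        has_cycle = any(v.kind == "parental-cycle" for v in validate(fb))
        assert has_cycle == has_cycle_oracle


class TestTime:
    def test_exists_at_half_open(self):
        p = Person("x", TimePoint(1990), TimePoint(2020))
        assert exists_at(p, TimePoint(2000))
        assert exists_at(p, TimePoint(1990))
        assert not exists_at(p, TimePoint(2020))
        assert not exists_at(p, TimePoint(1980))

    def test_unknown_bounds_are_permissive(self):
        assert exists_at(Person("x"), TimePoint(-(10**9)))
        assert exists_at(Person("x", birth=None, death=TimePoint(10)), TimePoint(5))

    def test_mixed_scales_raise(self):
        with pytest.raises(TimeScaleError):
            TimePoint(1990) < parse_timepoint("1990-01-01")

    def test_factbase_rejects_mixed_scales(self):
        fb = FactBase()
        fb.add_person(Person("a", TimePoint(1990)))
        with pytest.raises(TimeScaleError):
            fb.add_person(Person("b", parse_timepoint("1990-01-01")))

    def test_interval_overlap_half_open(self):
        a = TimeInterval(TimePoint(2000), TimePoint(2005))
        assert not a.overlaps(TimeInterval(TimePoint(2005), TimePoint(2010)))
        assert a.overlaps(TimeInterval(TimePoint(2004), None))


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_tabular_load_write_identity(self, seed, tmp_path):
        fb = generate_clean(seed, generations=3, founders=4)
        ped_p, uni_p = tmp_path / "p.tsv", tmp_path / "u.tsv"
        write_factbase(fb, str(ped_p), str(uni_p))
        assert load_pedigree(str(ped_p), str(uni_p)) == fb

    def test_empty_factbase_writes_headers(self, tmp_path):
        write_factbase(FactBase(), str(tmp_path / "p.tsv"), str(tmp_path / "u.tsv"))
        assert (tmp_path / "p.tsv").read_text().startswith("person_id\t")
        assert load_pedigree(str(tmp_path / "p.tsv"), str(tmp_path / "u.tsv")) == FactBase()

    def test_open_bond_renders_dot_and_rereads_open(self, tmp_path):
        fb = make_factbase(
            [("A", MALE, 1960), ("B", FEMALE, 1961)], bonds=[("m1", "A", "B", 1985)]
        )
        write_factbase(fb, str(tmp_path / "p.tsv"), str(tmp_path / "u.tsv"))
        assert "\t." in (tmp_path / "u.tsv").read_text()
        assert load_pedigree(str(tmp_path / "p.tsv"), str(tmp_path / "u.tsv")) == fb

    def test_json_carries_both_sex_bearer(self):
        fb = make_factbase([("snail", (MALE, FEMALE))])
        again = factbase_from_dict(factbase_to_dict(fb))
        assert again.sexes_of("snail") == {MALE, FEMALE}
        assert again == fb

    def test_tabular_dialect_rejects_both_sex_bearer(self, tmp_path):
        fb = make_factbase([("snail", (MALE, FEMALE))])
        with pytest.raises(ValueError, match="JSON"):
            write_factbase(fb, str(tmp_path / "p.tsv"), str(tmp_path / "u.tsv"))
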