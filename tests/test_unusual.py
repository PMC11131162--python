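"""The four unusual-situation detectors and the aggregated QC report."""

import pytest

from kinqc.model import FEMALE, MALE
from kinqc.simulate import generate_clean, inject
from kinqc.unusual import (
    ALERT_KINDS,
    CloseRelativePolicy,
    detect_ancestry_loop,
    detect_close_coparents,
    detect_close_spouses,
    detect_plural_spousal,
    qc_report,
    report_from_dict,
)

from .conftest import fred_bonds, loop_triples_oracle, make_factbase


class TestAncestryLoop:
    def test_chinatown_yields_exactly_one_triple(self, chinatown):
        [alert] = detect_ancestry_loop(chinatown)
        assert alert.participants == ("noah", "katherine", "evelyn")

    def test_clean_three_generations_yield_nothing(self):
        fb = make_factbase(
            [("a", MALE), ("b", FEMALE), ("c", MALE), ("d", FEMALE), ("e", None)],
            links=[("a", "c"), ("b", "c"), ("c", "e"), ("d", "e")],
        )
        assert detect_ancestry_loop(fb) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan_oracle(self, seed):
        fb = generate_clean(seed, generations=3, founders=4)
        fb2, _ = inject(fb, seed, "ancestry-loop", 1)
        for base in (fb, fb2):
            got = {a.participants for a in detect_ancestry_loop(base)}
            assert got == loop_triples_oracle(base)


class TestCloseCoparents:
    def test_sibling_coparents_flagged(self):
        fb = make_factbase(
            [("g", FEMALE), ("b", MALE), ("s", FEMALE), ("c", None)],
            links=[("g", "b"), ("g", "s"), ("b", "c"), ("s", "c")],
        )
        [alert] = detect_close_coparents(fb)
        assert alert.participants == ("b", "s", "c")

    def test_chinatown_coparents_are_parent_close(self, chinatown):
        [alert] = detect_close_coparents(chinatown)
        assert alert.participants == ("evelyn", "noah", "katherine")
        assert "parent" in alert.note

    def test_policy_controls_first_cousin_coparenting(self):
        fb = make_factbase(
            [
                ("g", FEMALE), ("p1", MALE), ("p2", FEMALE),
                ("c1", MALE), ("c2", FEMALE), ("kid", None),
            ],
            links=[
                ("g", "p1"), ("g", "p2"), ("p1", "c1"), ("p2", "c2"),
                ("c1", "kid"), ("c2", "kid"),
            ],
        )
        assert len(detect_close_coparents(fb)) == 1
        narrowed = CloseRelativePolicy(frozenset({"parent", "sibling"}))
        assert detect_close_coparents(fb, narrowed) == []

    def test_unrelated_coparents_pass(self, nuclear):
        assert detect_close_coparents(nuclear) == []


class TestCloseSpouses:
    def test_first_cousin_spouses_flagged(self):
        fb = make_factbase(
            [("g", FEMALE), ("p1", MALE), ("p2", FEMALE), ("c1", MALE), ("c2", FEMALE)],
            links=[("g", "p1"), ("g", "p2"), ("p1", "c1"), ("p2", "c2")],
            bonds=[("m1", "c1", "c2", 2000)],
        )
        [alert] = detect_close_spouses(fb)
        assert alert.participants == ("c1", "c2")

    def test_unrelated_spouses_pass(self, nuclear):
        assert detect_close_spouses(nuclear) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_policy_narrowing_is_monotone(self, seed):
        """alerts(narrower policy) is a subset of alerts(wider policy)."""
        fb, _ = inject(generate_clean(seed), seed, "close-relative-spouses", 1)
        wide = CloseRelativePolicy()
        for kept in ({"first-cousin"}, {"parent", "sibling"}, {"sibling"}):
            narrow = CloseRelativePolicy(frozenset(kept))
            wide_alerts = {a.participants for a in detect_close_spouses(fb, wide)}
            narrow_alerts = {a.participants for a in detect_close_spouses(fb, narrow)}
            assert narrow_alerts <= wide_alerts


class TestPluralSpousal:
    def test_contemporaneous_bonds_flagged(self):
        [alert] = detect_plural_spousal(fred_bonds(overlap=True))
        assert alert.participants == ("fred", "catherine", "sally")

    def test_serial_monogamy_passes(self):
        assert detect_plural_spousal(fred_bonds(overlap=False)) == []

    def test_remarriage_to_same_partner_passes(self):
        assert detect_plural_spousal(fred_bonds(overlap=True, same_partner=True)) == []


class TestQcReport:
    @pytest.mark.parametrize("seed", range(10))
    def test_clean_generator_triggers_nothing(self, seed):
        assert qc_report(generate_clean(seed, generations=3, founders=6)).clean

    @pytest.mark.parametrize("kind", ALERT_KINDS)
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_injection_recovery_is_exact(self, kind, k):
        """k disjoint injected anomalies are recovered exactly: the alert
        sets equal the injection manifest, kind by kind."""
        fb, manifest = inject(generate_clean(11), 23, kind, k)
        report = qc_report(fb)
        assert not report.violations
        got = {
            kk: sorted(a.participants for a in report.alerts if a.kind == kk)
            for kk in ALERT_KINDS
        }
        assert got == manifest.expected_alerts()
        assert report.counts[kind] == k

    def test_plural_spousal_detector_can_be_disabled(self):
        fb = fred_bonds(overlap=True)
        assert len(qc_report(fb).alerts) == 1
        assert qc_report(fb, plural_spousal=False).clean

    def test_alert_support_resatisfies_pattern(self, chinatown):
        """Every alert's participants re-satisfy the defining pattern."""
        from kinqc import inference as inf

        for alert in qc_report(chinatown).alerts:
            if alert.kind == "ancestry-loop":
                x, y, z = alert.participants
                assert inf.natural_parent_of(chinatown, x, y)
                assert inf.natural_ancestor_of(chinatown, x, z)
                assert inf.natural_ancestor_of(chinatown, z, y)
            elif alert.kind == "close-relative-coparents":
                x, y, z = alert.participants
                assert inf.natural_parent_of(chinatown, x, z)
                assert inf.natural_parent_of(chinatown, y, z)
                assert CloseRelativePolicy().close(chinatown, x, y)

    def test_report_round_trips_through_json(self):
        import json

        fb, _ = inject(generate_clean(3), 5, "plural-spousal", 2)
        report = qc_report(fb)
        again = report_from_dict(json.loads(report.to_json()))
        assert again.alerts == report.alerts
        assert again.violations == report.violations
        assert again.counts == report.counts

    def test_cyclic_factbase_reports_violations_only(self):
        fb = make_factbase([("a", None), ("b", None)], links=[("a", "b"), ("b", "a")])
        report = qc_report(fb)
        assert [v.kind for v in report.violations] == ["parental-cycle"]
        assert report.alerts == []
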