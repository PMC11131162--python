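"""Detectors for the four "unusual situation" alert patterns.

An unusual situation is an atypical-but-possible kinship pattern — unusual
means *atypical*, never *bad*: the alerts carry no normative weight.  They
exist because such patterns occur rarely enough in family-history registries
that, when one appears, the triggering data entry is often a mistake and is
worth double-checking.

The four kinds:

* ``ancestry-loop`` — a person has a natural child who is also a natural
  descendant of one of that person's own natural descendants (the classic
  *Chinatown* scenario: fathering a child with one's own daughter).
* ``close-relative-coparents`` — two close blood relatives are co-natural
  parents of a common person.
* ``close-relative-spouses`` — two close blood relatives are spouses.
* ``plural-spousal`` — one person carries two contemporaneous marriage bonds
  to two distinct partners.

Which blood relations count as "close" is a tunable policy: the default set
is {parent, sibling, grandparent, aunt, uncle, first-cousin}, and closeness
is evaluated symmetrically (either argument order).  Narrowing the policy can
only remove alerts; widening it (say, down to seventh cousins) would flood a
registry with false positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

from . import inference as inf
from .model import FactBase, IntegrityViolation, validate

NON_NORMATIVE_NOTE = (
    "'Unusual' means atypical, not bad: these alerts recommend double-checking "
    "the entered data and carry no normative weight."
)

#: predicate registry backing CloseRelativePolicy; extensible by callers
CLOSE_PREDICATES: dict[str, Callable[[FactBase, str, str], bool]] = {
    "parent": inf.natural_parent_of,
    "sibling": inf.natural_sibling_of,
    "grandparent": inf.natural_grandparent_of,
    "aunt": inf.natural_aunt_of,
    "uncle": inf.natural_uncle_of,
    "first-cousin": inf.natural_first_cousin_of,
}

DEFAULT_CLOSE_PREDICATES = frozenset(CLOSE_PREDICATES)


@dataclass(frozen=True)
class CloseRelativePolicy:
    """The set of blood relations that qualify as *close*."""

    predicates: frozenset[str] = DEFAULT_CLOSE_PREDICATES

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ValueError("a close-relative policy must enable at least one predicate")
        unknown = self.predicates - set(CLOSE_PREDICATES)
        if unknown:
            raise ValueError(f"unknown close-relative predicates: {sorted(unknown)}")

    def close(self, fb: FactBase, x: str, y: str) -> list[str]:
        """Names of enabled predicates holding between x and y in either
        argument order (blood-closeness is symmetric)."""
        hits = []
        for name in sorted(self.predicates):
            pred = CLOSE_PREDICATES[name]
            if pred(fb, x, y) or pred(fb, y, x):
                hits.append(name)
        return hits


DEFAULT_POLICY = CloseRelativePolicy()


@dataclass(frozen=True)
class UnusualSituation:
    kind: str  # ancestry-loop | close-relative-coparents |
    #            close-relative-spouses | plural-spousal
    participants: tuple[str, ...]
    support: tuple[tuple, ...] = ()
    note: str = ""

    def sort_key(self):
        return (self.kind, self.participants)


def detect_ancestry_loop(fb: FactBase) -> list[UnusualSituation]:
    """Triples (x, y, z): x has natural child y, and some natural descendant
    z of x is a natural ancestor of y."""
    anc = inf.ancestor_closure(fb)
    out = []
    for link in sorted(fb.parent_links, key=lambda l: (l.parent, l.child)):
        x, y = link.parent, link.child
        for z in sorted(fb.persons):
            if (x, z) in anc and (z, y) in anc:
                out.append(
                    UnusualSituation(
                        "ancestry-loop",
                        (x, y, z),
                        support=(
                            ("has-natural-child", x, y),
                            ("natural-ancestor-of", x, z),
                            ("natural-ancestor-of", z, y),
                        ),
                        note=f"{x} has child {y} with own descendant {z}",
                    )
                )
    return sorted(out, key=UnusualSituation.sort_key)


def detect_close_coparents(
    fb: FactBase, policy: CloseRelativePolicy = DEFAULT_POLICY
) -> list[UnusualSituation]:
    """Triples (x, y, z): x and y are both natural parents of z and are close
    blood relatives; each unordered co-parent pair is reported once per
    child."""
    inf.ancestor_closure(fb)  # raises on cycles before any policy evaluation
    out = []
    for z in sorted({l.child for l in fb.parent_links}):
        parents = sorted(fb.parents_of(z))
        for i, x in enumerate(parents):
            for y in parents[i + 1 :]:
                hits = policy.close(fb, x, y)
                if hits:
                    out.append(
                        UnusualSituation(
                            "close-relative-coparents",
                            (x, y, z),
                            support=(
                                ("has-natural-child", x, z),
                                ("has-natural-child", y, z),
                                ("close-blood-relatives", x, y, ",".join(hits)),
                            ),
                            note=f"co-parents {x},{y} of {z} are close ({', '.join(hits)})",
                        )
                    )
    return sorted(out, key=UnusualSituation.sort_key)


def detect_close_spouses(
    fb: FactBase, policy: CloseRelativePolicy = DEFAULT_POLICY
) -> list[UnusualSituation]:
    """Unordered spouse pairs {x, y} joined by some bond who are close blood
    relatives."""
    inf.ancestor_closure(fb)
    seen: dict[tuple[str, str], list[str]] = {}
    for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id):
        a, b = bond.partners
        if a == b:
            continue  # a self-spouse is an integrity violation, not an alert
        seen.setdefault((a, b), []).append(bond.id)
    out = []
    for (a, b), bond_ids in sorted(seen.items()):
        hits = policy.close(fb, a, b)
        if hits:
            out.append(
                UnusualSituation(
                    "close-relative-spouses",
                    (a, b),
                    support=tuple(("marriage-bond", bid, a, b) for bid in bond_ids)
                    + (("close-blood-relatives", a, b, ",".join(hits)),),
                    note=f"spouses {a},{b} are close blood relatives ({', '.join(hits)})",
                )
            )
    return sorted(out, key=UnusualSituation.sort_key)


def detect_plural_spousal(fb: FactBase) -> list[UnusualSituation]:
    """Triples (x, y, z), y != z, with two marriage bonds joining x to y and
    x to z whose half-open intervals share at least one time point.  Serial
    monogamy (disjoint intervals) and remarriage to the same partner never
    trigger."""
    out: dict[tuple[str, str, str], UnusualSituation] = {}
    for x in sorted(fb.persons):
        bonds = [b for b in fb.bonds_of(x) if b.partners[0] != b.partners[1]]
        for i, m1 in enumerate(bonds):
            for m2 in bonds[i + 1 :]:
                y, z = m1.other(x), m2.other(x)
                if y == z or not m1.interval.overlaps(m2.interval):
                    continue
                key = (x, *sorted((y, z)))
                out.setdefault(
                    key,
                    UnusualSituation(
                        "plural-spousal",
                        key,
                        support=(
                            ("marriage-bond", m1.id, *m1.partners),
                            ("marriage-bond", m2.id, *m2.partners),
                        ),
                        note=f"{x} holds contemporaneous bonds to {key[1]} and {key[2]}",
                    ),
                )
    return sorted(out.values(), key=UnusualSituation.sort_key)


ALERT_KINDS = (
    "ancestry-loop",
    "close-relative-coparents",
    "close-relative-spouses",
    "plural-spousal",
)


@dataclass
class AlertReport:
    """Aggregated QC output: integrity violations plus all unusual-situation
    alerts, with deterministic ordering and per-kind counts."""

    violations: list[IntegrityViolation] = field(default_factory=list)
    alerts: list[UnusualSituation] = field(default_factory=list)
    note: str = NON_NORMATIVE_NOTE

    @property
    def counts(self) -> dict[str, int]:
        counts = {kind: 0 for kind in ALERT_KINDS}
        for a in self.alerts:
            counts[a.kind] += 1
        counts["integrity-violations"] = len(self.violations)
        return counts

    @property
    def clean(self) -> bool:
        return not self.violations and not self.alerts

    def to_dict(self) -> dict:
        return {
            "note": self.note,
            "counts": self.counts,
            "violations": [
                {"kind": v.kind, "participants": list(v.participants), "note": v.note}
                for v in self.violations
            ],
            "alerts": [
                {
                    "kind": a.kind,
                    "participants": list(a.participants),
                    "support": [list(atom) for atom in a.support],
                    "note": a.note,
                }
                for a in self.alerts
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        lines = ["kind\tparticipants\tnote"]
        for v in self.violations:
            lines.append(f"violation:{v.kind}\t{','.join(v.participants)}\t{v.note}")
        for a in self.alerts:
            lines.append(f"{a.kind}\t{','.join(a.participants)}\t{a.note}")
        return "\n".join(lines) + "\n"


ALERT_REPORT_SCHEMA: dict = {
    "$id": "kinqc/alert-report.schema.json",
    "type": "object",
    "required": ["note", "counts", "violations", "alerts"],
    "properties": {
        "note": {"type": "string"},
        "counts": {"type": "object"},
        "violations": {"type": "array"},
        "alerts": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["kind", "participants"],
                "properties": {"kind": {"enum": list(ALERT_KINDS)}},
            },
        },
    },
}


def report_from_dict(data: dict) -> AlertReport:
    """Rebuild an AlertReport from its JSON form (round-trip support)."""
    return AlertReport(
        violations=[
            IntegrityViolation(v["kind"], tuple(v["participants"]), v.get("note", ""))
            for v in data["violations"]
        ],
        alerts=[
            UnusualSituation(
                a["kind"],
                tuple(a["participants"]),
                tuple(tuple(atom) for atom in a.get("support", [])),
                a.get("note", ""),
            )
            for a in data["alerts"]
        ],
        note=data.get("note", NON_NORMATIVE_NOTE),
    )


def qc_report(
    fb: FactBase,
    policy: CloseRelativePolicy = DEFAULT_POLICY,
    *,
    plural_spousal: bool = True,
) -> AlertReport:
    """Run all detectors plus the integrity checks.

    ``plural_spousal=False`` disables that detector entirely (appropriate
    where plural marriage is ordinary rather than atypical).  A cyclic parent
    graph yields the integrity violations only — ancestry-based detectors are
    undefined on it.
    """
    violations = validate(fb)
    if any(v.kind in ("self-parent", "parental-cycle") for v in violations):
        return AlertReport(violations=violations, alerts=[])
    alerts = (
        detect_ancestry_loop(fb)
        + detect_close_coparents(fb, policy)
        + detect_close_spouses(fb, policy)
        + (detect_plural_spousal(fb) if plural_spousal else [])
    )
    return AlertReport(violations=violations, alerts=sorted(alerts, key=UnusualSituation.sort_key))
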