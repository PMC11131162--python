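"""Shared fixtures: hand-built worked-example pedigrees and independent
oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from kinqc.model import (
    FEMALE,
    MALE,
    FactBase,
    MarriageBond,
    ParentLink,
    Person,
    SexQuality,
    TimeInterval,
    TimePoint,
)


def make_factbase(
    persons: list[tuple],  # (id, sex|None[, birth[, death]])
    links: list[tuple[str, str]] = (),
    bonds: list[tuple] = (),  # (bond_id, a, b, start[, end])
) -> FactBase:
    fb = FactBase()
    for row in persons:
        pid, sex, *times = row
        birth = TimePoint(times[0]) if times and times[0] is not None else None
        death = TimePoint(times[1]) if len(times) > 1 and times[1] is not None else None
        fb.add_person(Person(pid, birth, death))
        if sex is not None:
            for value in sex if isinstance(sex, tuple) else (sex,):
                fb.add_sex_quality(SexQuality(pid, value))
    for parent, child in links:
        fb.add_parent_link(ParentLink(parent, child))
    for row in bonds:
        bond_id, a, b, start, *rest = row
        end = TimePoint(rest[0]) if rest and rest[0] is not None else None
        fb.add_marriage_bond(MarriageBond(bond_id, (a, b), TimeInterval(TimePoint(start), end)))
    return fb


@pytest.fixture
def chinatown() -> FactBase:
    """A father who also fathered a child with his own daughter: noah is
    parent of evelyn (with mara) and co-parent, with evelyn, of katherine."""
    return make_factbase(
        persons=[
            ("noah", MALE, 1900),
            ("mara", FEMALE, 1902),
            ("evelyn", FEMALE, 1925),
            ("katherine", FEMALE, 1945),
        ],
        links=[
            ("noah", "evelyn"),
            ("mara", "evelyn"),
            ("noah", "katherine"),
            ("evelyn", "katherine"),
        ],
    )


def fred_bonds(*, overlap: bool, same_partner: bool = False) -> FactBase:
    """Fred with two marriage bonds: contemporaneous, serial, or a remarriage
    to the same partner."""
    second = "sally" if not same_partner else "catherine"
    intervals = {
        True: [("m1", "fred", "catherine", 1990, None), ("m2", "fred", second, 2000, None)],
        False: [("m1", "fred", "catherine", 1990, 1999), ("m2", "fred", second, 2000, None)],
    }
    return make_factbase(
        persons=[("fred", MALE, 1960), ("catherine", FEMALE, 1962), ("sally", FEMALE, 1965)],
        bonds=intervals[overlap],
    )


@pytest.fixture
def nuclear() -> FactBase:
    """Father, mother (married), son and daughter."""
    return make_factbase(
        persons=[("f", MALE, 1960), ("m", FEMALE, 1962), ("a", MALE, 1985), ("b", FEMALE, 1988)],
        links=[("f", "a"), ("f", "b"), ("m", "a"), ("m", "b")],
        bonds=[("m1", "f", "m", 1984, None)],
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def closure_oracle(fb: FactBase) -> set[tuple[str, str]]:
    """Transitive closure of the parent->child relation by boolean matrix
    squaring — independent of the graph-traversal implementation."""
    ids = sorted(fb.persons)
    index = {p: i for i, p in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for link in fb.parent_links:
        adj[index[link.parent], index[link.child]] = True
    reach = adj.copy()
    while True:
        nxt = reach | (reach @ adj)
        if (nxt == reach).all():
            break
        reach = nxt
    return {(ids[i], ids[j]) for i, j in zip(*np.nonzero(reach))}


def loop_triples_oracle(fb: FactBase) -> set[tuple[str, str, str]]:
    """Exhaustive scan for ancestry-loop triples over the closure oracle."""
    reach = closure_oracle(fb)
    return {
        (l.parent, l.child, z)
        for l in fb.parent_links
        for z in fb.persons
        if (l.parent, z) in reach and (z, l.child) in reach
    }
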