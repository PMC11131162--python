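"""Seeded synthetic pedigrees and targeted anomaly injection.

The clean generator produces a registry-style pedigree with none of the four
unusual situations and no integrity violations: founder couples, each child
with exactly one male-sexed and one female-sexed parent, strictly
parent-before-child integer-tick births, and strict monogamy in which every
married-in spouse is an unrelated outsider (so spouses and co-parents are
never close blood relatives by construction).  Members of the final
generation stay unmarried.

Anomaly injection then plants a known number of disjoint unusual situations
and returns a manifest of every alert the detectors are expected to raise —
the ground truth for detector soundness/completeness tests.  Note that one
injected situation can entail alerts of more than one kind: a parent
co-parenting with their own child is both an ancestry loop and a
close-relative co-parenting; the manifest lists both.

Randomness discipline: the single seed is split into one child stream per
generator stage (sexes, fertility, marriage, birth jitter, injection
choices), so adding a stage never perturbs the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .model import (
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
from .unusual import ALERT_KINDS

GENERATION_GAP = 20  # ticks between a parent's and first child's births


@dataclass
class InjectionManifest:
    """Expected detector output for a set of injected anomalies."""

    kind: str
    count: int
    expected: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def expected_alerts(self) -> dict[str, list[tuple[str, ...]]]:
        """All four kinds, absent ones as empty lists, participant tuples
        sorted as the detectors sort them."""
        return {k: sorted(self.expected.get(k, [])) for k in ALERT_KINDS}

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "count": self.count,
            "expected": {k: [list(t) for t in v] for k, v in self.expected_alerts().items()},
        }


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_clean(
    seed: int,
    generations: int = 4,
    founders: int = 8,
    mean_children: float = 2.5,
    marriage_rate: float = 0.8,
) -> FactBase:
    """Generate a clean pedigree: deterministic per seed, free of integrity
    violations and of all four unusual situations.

    ``founders`` is the number of founder individuals (paired into couples,
    so it must be even and >= 2); ``mean_children`` is the mean sibship size
    per couple (>= 1; every couple has at least one child); ``marriage_rate``
    is the probability that a non-final-generation member marries (an
    unrelated outsider).  Births are integer ticks, distinct within each
    sibship so that age-ordered aunt/uncle relations are determinate.
    """
    if generations < 1:
        raise GenerationError("generations must be >= 1")
    if founders < 2 or founders % 2:
        raise GenerationError("founders must be an even number >= 2")
    if mean_children < 1:
        raise GenerationError("mean_children must be >= 1 (every couple has a child)")
    if not 0 <= marriage_rate <= 1:
        raise GenerationError("marriage_rate must lie in [0, 1]")

    rng_sex, rng_fert, rng_marr, rng_birth = _streams(seed, 4)
    fb = FactBase()
    counter = 0

    def new_person(sex: str, birth: int) -> str:
        nonlocal counter
        counter += 1
        pid = f"P{counter:04d}"
        fb.add_person(Person(pid, TimePoint(birth)))
        fb.add_sex_quality(SexQuality(pid, sex))
        return pid

    def marry(a: str, b: str) -> None:
        start = max(fb.persons[a].birth.value, fb.persons[b].birth.value) + GENERATION_GAP
        bond_id = f"M{len(fb.marriage_bonds) + 1:04d}"
        fb.add_marriage_bond(MarriageBond(bond_id, (a, b), TimeInterval(TimePoint(start))))

    couples: list[tuple[str, str]] = []
    for _ in range(founders // 2):
        birth_m = int(rng_birth.integers(-5, 6))
        birth_f = int(rng_birth.integers(-5, 6))
        husband = new_person(MALE, birth_m)
        wife = new_person(FEMALE, birth_f)
        marry(husband, wife)
        couples.append((husband, wife))

    for gen in range(1, generations):
        children: list[str] = []
        for a, b in couples:
            n_children = 1 + int(rng_fert.poisson(mean_children - 1))
            base = max(fb.persons[a].birth.value, fb.persons[b].birth.value) + GENERATION_GAP
            for i in range(n_children):
                sex = MALE if rng_sex.random() < 0.5 else FEMALE
                child = new_person(sex, base + 2 * i + int(rng_birth.integers(0, 2)))
                fb.add_parent_link(ParentLink(a, child))
                fb.add_parent_link(ParentLink(b, child))
                children.append(child)
        if gen == generations - 1:
            break  # the final generation stays unmarried
        next_couples: list[tuple[str, str]] = []
        marrying = [c for c in children if rng_marr.random() < marriage_rate]
        if not marrying and children:
            marrying = [children[0]]  # keep the pedigree growing
        for member in marrying:
            member_sex = MALE if MALE in fb.sexes_of(member) else FEMALE
            spouse_sex = FEMALE if member_sex == MALE else MALE
            spouse = new_person(
                spouse_sex, fb.persons[member].birth.value + int(rng_birth.integers(-3, 4))
            )
            marry(member, spouse)
            next_couples.append(
                (member, spouse) if member_sex == MALE else (spouse, member)
            )
        couples = next_couples
    return fb


# ---------------------------------------------------------------------------
# anomaly injection
# ---------------------------------------------------------------------------


def _founder_couples(fb: FactBase) -> list[tuple[str, str]]:
    """Couples in which both partners are founders (no recorded parents)."""
    out = []
    for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id):
        a, b = bond.partners
        if not fb.parents_of(a) and not fb.parents_of(b):
            out.append((a, b) if MALE in fb.sexes_of(a) else (b, a))
    return out


def _pick(rng: np.random.Generator, candidates: list, count: int, kind: str) -> list:
    if len(candidates) < count:
        raise GenerationError(
            f"pedigree too small to host {count} disjoint {kind} anomalies "
            f"({len(candidates)} candidate sites)"
        )
    idx = sorted(rng.choice(len(candidates), size=count, replace=False).tolist())
    return [candidates[i] for i in idx]


def inject(fb: FactBase, seed: int, kind: str, count: int) -> tuple[FactBase, InjectionManifest]:
    """Add ``count`` disjoint anomalies of ``kind`` to a copy of ``fb``.

    Kinds: ``ancestry-loop`` (a founder father co-parents a child with his
    own daughter), ``close-relative-coparents`` (a brother-sister pair gains
    a common child), ``close-relative-spouses`` (two unmarried first cousins
    gain a bond), ``plural-spousal`` (a married person gains a second,
    contemporaneous bond to a new outsider).  Returns the modified copy and
    the manifest of every expected alert.  count=0 returns an unchanged copy.
    """
    if kind not in ALERT_KINDS:
        raise GenerationError(f"unknown anomaly kind {kind!r}; choose from {ALERT_KINDS}")
    if count < 0:
        raise GenerationError("count must be >= 0")
    out = fb.copy()
    manifest = InjectionManifest(kind, count)
    if count == 0:
        return out, manifest
    (rng,) = _streams(seed, 1)
    expected: dict[str, list[tuple[str, ...]]] = {}

    def expect(alert_kind: str, participants: tuple[str, ...]) -> None:
        expected.setdefault(alert_kind, []).append(participants)

    if kind == "ancestry-loop":
        sites = []
        for father, mother in _founder_couples(fb):
            daughters = sorted(
                c
                for c in fb.children_of(father) & fb.children_of(mother)
                if FEMALE in fb.sexes_of(c)
            )
            if daughters:
                sites.append((father, daughters[0]))
        for i, (father, daughter) in enumerate(_pick(rng, sites, count, kind), start=1):
            child = f"LOOP{i:03d}"
            birth = out.persons[daughter].birth
            out.add_person(
                Person(child, None if birth is None else TimePoint(birth.value + GENERATION_GAP))
            )
            out.add_sex_quality(SexQuality(child, FEMALE))
            out.add_parent_link(ParentLink(father, child))
            out.add_parent_link(ParentLink(daughter, child))
            expect("ancestry-loop", (father, child, daughter))
            # the co-parents are parent and child: also a close-relative pair
            expect("close-relative-coparents", (*sorted((father, daughter)), child))

    elif kind == "close-relative-coparents":
        sites = []
        seen_parents: set[str] = set()
        for father, mother in _couples_with_children(fb):
            kids = sorted(fb.children_of(father) & fb.children_of(mother))
            brothers = [c for c in kids if MALE in fb.sexes_of(c)]
            sisters = [c for c in kids if FEMALE in fb.sexes_of(c)]
            if brothers and sisters and not {brothers[0], sisters[0]} & seen_parents:
                sites.append((brothers[0], sisters[0]))
                seen_parents |= {brothers[0], sisters[0]}
        for i, (brother, sister) in enumerate(_pick(rng, sites, count, kind), start=1):
            child = f"CRCP{i:03d}"
            birth = max(out.persons[brother].birth.value, out.persons[sister].birth.value)
            out.add_person(Person(child, TimePoint(birth + GENERATION_GAP)))
            out.add_sex_quality(SexQuality(child, MALE))
            out.add_parent_link(ParentLink(brother, child))
            out.add_parent_link(ParentLink(sister, child))
            expect("close-relative-coparents", (*sorted((brother, sister)), child))

    elif kind == "close-relative-spouses":
        sites = []
        used: set[str] = set()
        for c1, c2 in _unmarried_first_cousins(fb):
            if not {c1, c2} & used:
                sites.append((c1, c2))
                used |= {c1, c2}
        for i, (c1, c2) in enumerate(_pick(rng, sites, count, kind), start=1):
            start = (
                max(out.persons[c1].birth.value, out.persons[c2].birth.value) + GENERATION_GAP
            )
            out.add_marriage_bond(
                MarriageBond(f"CRSP{i:03d}", (c1, c2), TimeInterval(TimePoint(start)))
            )
            expect("close-relative-spouses", tuple(sorted((c1, c2))))

    elif kind == "plural-spousal":
        sites = []
        used: set[str] = set()
        for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id):
            if bond.interval.end is None:
                a, b = bond.partners
                if len(fb.bonds_of(a)) == 1 and not {a, b} & used:
                    sites.append((a, b, bond))
                    used |= {a, b}
        for i, (x, y, bond) in enumerate(_pick(rng, sites, count, kind), start=1):
            z = f"PLSP{i:03d}"
            out.add_person(Person(z, TimePoint(out.persons[x].birth.value)))
            out.add_sex_quality(SexQuality(z, FEMALE if MALE in fb.sexes_of(x) else MALE))
            start = bond.interval.start.value + 5
            out.add_marriage_bond(
                MarriageBond(f"PLBD{i:03d}", (x, z), TimeInterval(TimePoint(start)))
            )
            expect("plural-spousal", (x, *sorted((y, z))))

    manifest.expected = expected
    return out, manifest


def _couples_with_children(fb: FactBase) -> list[tuple[str, str]]:
    out = []
    for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id):
        a, b = bond.partners
        if fb.children_of(a) & fb.children_of(b):
            out.append((a, b) if MALE in fb.sexes_of(a) else (b, a))
    return out


def _unmarried_first_cousins(fb: FactBase) -> list[tuple[str, str]]:
    """Unmarried pairs whose member parents are full siblings (sorted)."""
    unmarried = [p for p in sorted(fb.persons) if not fb.bonds_of(p)]
    out = []
    for i, c1 in enumerate(unmarried):
        for c2 in unmarried[i + 1 :]:
            if fb.parents_of(c1) & fb.parents_of(c2):
                continue  # siblings, not cousins
            linked = any(
                p1 != p2 and (fb.parents_of(p1) & fb.parents_of(p2))
                for p1 in fb.parents_of(c1)
                for p2 in fb.parents_of(c2)
            )
            if linked:
                out.append((c1, c2))
    return out
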