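"""The kinship ontology as a Horn rule base, plus ground-fact extraction.

This is the declarative twin of :mod:`kinqc.inference` and
:mod:`kinqc.unusual`: the same relation definitions and unusual-situation
axioms, but expressed as Kowalski rules and evaluated by the forward-chaining
engine.  Equality of the two routes over shared predicates is the package's
central self-check.

Existential structure in the axioms (a sex quality inhering in a person, a
marriage bond inhering in two persons at a time) is pre-skolemized at fact
extraction: the quality and bond facts *are* the Skolem witnesses.  Temporal
arithmetic (birth ordering, bond-interval overlap) and the one closed-world
condition (the first-cousin definition's sibling exclusion) are likewise
pre-computed into ground facts, keeping the rule base negation-free.
"""

from __future__ import annotations

from .engine import AND, OR, Atom, KowalskiRule, to_kowalski
from .model import FEMALE, MALE, FactBase
from .unusual import DEFAULT_POLICY, CloseRelativePolicy

# variable shorthands
X, Y, Z, P, Q, S, PX, PY, M1, M2 = "?x ?y ?z ?p ?q ?s ?px ?py ?m1 ?m2".split()


def ground_facts(fb: FactBase, *, full_siblings_only: bool = False) -> set[Atom]:
    """Extract the pre-skolemized ground atoms the rule base runs on.

    Emitted predicates: has-natural-child/2, sex-quality/2, bond-joins/3
    (bond id, a partner, the other partner; both orders; self-bonds skipped),
    bonds-overlap/2 (distinct bonds of a common partner with intersecting
    half-open intervals; both orders), birth-before/2 (pairs with known
    births), distinct/2, and not-natural-sibling-of/2 — the closed-world
    complement of siblinghood over distinct pairs, computed directly from the
    parent links.
    """
    facts: set[Atom] = set()
    people = sorted(fb.persons)
    for link in fb.parent_links:
        facts.add(("has-natural-child", link.parent, link.child))
    for q in fb.sex_qualities:
        facts.add(("sex-quality", q.bearer, q.value))
    for bond in fb.marriage_bonds.values():
        a, b = bond.partners
        if a == b:
            continue
        facts.add(("bond-joins", bond.id, a, b))
        facts.add(("bond-joins", bond.id, b, a))
    bonds = [b for b in fb.marriage_bonds.values() if b.partners[0] != b.partners[1]]
    for i, m1 in enumerate(bonds):
        for m2 in bonds[i + 1 :]:
            if set(m1.partners) & set(m2.partners) and m1.interval.overlaps(m2.interval):
                facts.add(("bonds-overlap", m1.id, m2.id))
                facts.add(("bonds-overlap", m2.id, m1.id))
    for x in people:
        bx = fb.persons[x].birth
        for y in people:
            if x == y:
                continue
            facts.add(("distinct", x, y))
            by = fb.persons[y].birth
            if bx is not None and by is not None and bx < by:
                facts.add(("birth-before", x, y))
            if not _siblings(fb, x, y, full_siblings_only):
                facts.add(("not-natural-sibling-of", x, y))
    return facts


def _siblings(fb: FactBase, x: str, y: str, full: bool) -> bool:
    shared = fb.parents_of(x) & fb.parents_of(y)
    if not shared:
        return False
    if not full:
        return True
    return any(MALE in fb.sexes_of(p) for p in shared) and any(
        FEMALE in fb.sexes_of(p) for p in shared
    )


def _r(head: Atom, *body: Atom) -> KowalskiRule:
    rule = KowalskiRule(tuple(body), head)
    rule.check_safe()
    return rule


def kinship_rules(*, full_siblings_only: bool = False) -> list[KowalskiRule]:
    """Horn rules deriving every relation that infer_all materialises."""
    hnc = lambda a, b: ("has-natural-child", a, b)
    sib = lambda a, b: ("natural-sibling-of", a, b)
    sex = lambda a, v: ("sex-quality", a, v)
    rules = [
        _r(("natural-parent-of", X, Y), hnc(X, Y)),
        _r(("natural-father-of", X, Y), hnc(X, Y), sex(X, MALE)),
        _r(("natural-mother-of", X, Y), hnc(X, Y), sex(X, FEMALE)),
        # recursive ancestry: base and step
        _r(("natural-ancestor-of", X, Y), hnc(X, Y)),
        _r(("natural-ancestor-of", X, Z), hnc(X, Y), ("natural-ancestor-of", Y, Z)),
        _r(("natural-grandparent-of", X, Y), hnc(X, P), hnc(P, Y)),
        _r(("natural-maternal-grandparent-of", X, Y), hnc(X, P), hnc(P, Y), sex(P, FEMALE)),
        _r(("natural-paternal-grandparent-of", X, Y), hnc(X, P), hnc(P, Y), sex(P, MALE)),
        _r(("natural-aunt-of", X, Y), sib(X, P), hnc(P, Y), sex(X, FEMALE)),
        _r(("natural-uncle-of", X, Y), sib(X, P), hnc(P, Y), sex(X, MALE)),
        _r(
            ("natural-older-aunt-of", X, Y),
            sib(X, P), hnc(P, Y), sex(X, FEMALE), ("birth-before", X, P),
        ),
        _r(
            ("natural-younger-aunt-of", X, Y),
            sib(X, P), hnc(P, Y), sex(X, FEMALE), ("birth-before", P, X),
        ),
        _r(
            ("natural-older-uncle-of", X, Y),
            sib(X, P), hnc(P, Y), sex(X, MALE), ("birth-before", X, P),
        ),
        _r(
            ("natural-younger-uncle-of", X, Y),
            sib(X, P), hnc(P, Y), sex(X, MALE), ("birth-before", P, X),
        ),
        _r(("natural-niece-of", X, Y), hnc(S, X), sib(S, Y), sex(X, FEMALE)),
        _r(("natural-nephew-of", X, Y), hnc(S, X), sib(S, Y), sex(X, MALE)),
        _r(
            ("natural-first-cousin-of", X, Y),
            hnc(PX, X), hnc(PY, Y), sib(PX, PY), ("not-natural-sibling-of", X, Y),
        ),
        _r(("has-spouse", X, Y), ("bond-joins", M1, X, Y)),
    ]
    if full_siblings_only:
        rules.append(
            _r(
                sib(X, Y),
                hnc(P, X), hnc(P, Y), sex(P, MALE),
                hnc(Q, X), hnc(Q, Y), sex(Q, FEMALE),
                ("distinct", X, Y),
            )
        )
    else:
        rules.append(_r(sib(X, Y), hnc(P, X), hnc(P, Y), ("distinct", X, Y)))
    return rules


# ---------------------------------------------------------------------------
# the four unusual-situation axioms, in implication form
# ---------------------------------------------------------------------------


def ancestry_loop_axiom() -> tuple[object, Atom]:
    """has-natural-child(x,y) & ancestor(x,z) & ancestor(z,y) -> loop(x,y,z)."""
    body = (
        AND,
        ("has-natural-child", X, Y),
        ("natural-ancestor-of", X, Z),
        ("natural-ancestor-of", Z, Y),
    )
    return body, ("unusual-ancestry-loop", X, Y, Z)


def close_coparents_axiom(
    policy: CloseRelativePolicy = DEFAULT_POLICY, *, symmetric: bool = True
) -> tuple[object, Atom]:
    """Co-parents of a common person who are close blood relatives.

    As printed, the defining disjunction lists parent/sibling/grandparent/
    first-cousin over (x, y) but aunt/uncle over (y, x); with
    ``symmetric=True`` (the operational reading: blood-closeness does not
    depend on argument order) every enabled predicate contributes both
    orders.
    """
    disjuncts = _close_disjuncts(policy, symmetric)
    body = (
        AND,
        ("has-natural-child", X, Z),
        ("has-natural-child", Y, Z),
        (OR, *disjuncts),
    )
    return body, ("unusual-close-coparents", X, Y, Z)


def close_spouses_axiom(
    policy: CloseRelativePolicy = DEFAULT_POLICY, *, symmetric: bool = True
) -> tuple[object, Atom]:
    """Spouses who are close blood relatives (mirrors the co-parent
    disjunction)."""
    body = (AND, ("has-spouse", X, Y), (OR, *_close_disjuncts(policy, symmetric)))
    return body, ("unusual-close-spouses", X, Y)


def plural_spousal_axiom() -> tuple[object, Atom]:
    """Two contemporaneous bonds of one person to distinct partners.

    The shared time point and the two bond instances are the pre-skolemized
    bond-joins / bonds-overlap facts.
    """
    body = (
        AND,
        ("bond-joins", M1, X, Y),
        ("bond-joins", M2, X, Z),
        ("bonds-overlap", M1, M2),
        ("distinct", Y, Z),
    )
    return body, ("unusual-plural-spousal", X, Y, Z)


_CLOSE_ATOMS = {
    "parent": "natural-parent-of",
    "sibling": "natural-sibling-of",
    "grandparent": "natural-grandparent-of",
    "aunt": "natural-aunt-of",
    "uncle": "natural-uncle-of",
    "first-cousin": "natural-first-cousin-of",
}

#: argument order of each disjunct as printed in the co-parent axiom:
#: aunt/uncle take (y, x), the rest (x, y)
PRINTED_FLIPPED = frozenset({"aunt", "uncle"})


def _close_disjuncts(policy: CloseRelativePolicy, symmetric: bool) -> list[Atom]:
    out = []
    for name in sorted(policy.predicates):
        pred = _CLOSE_ATOMS[name]
        if symmetric:
            out.append((pred, X, Y))
            out.append((pred, Y, X))
        else:
            out.append((pred, Y, X) if name in PRINTED_FLIPPED else (pred, X, Y))
    return out


def unusual_rules(
    policy: CloseRelativePolicy = DEFAULT_POLICY, *, plural_spousal: bool = True
) -> list[KowalskiRule]:
    """The four alert axioms compiled to Horn rules (disjunctions split)."""
    axioms = [
        ancestry_loop_axiom(),
        close_coparents_axiom(policy),
        close_spouses_axiom(policy),
    ]
    if plural_spousal:
        axioms.append(plural_spousal_axiom())
    rules = []
    for body, head in axioms:
        rules.extend(to_kowalski(body, head))
    return rules


def irreflexive_ancestor_constraint() -> KowalskiRule:
    """No one is their own natural ancestor — the adopted hard constraint."""
    return KowalskiRule((("natural-ancestor-of", X, X),), None)
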