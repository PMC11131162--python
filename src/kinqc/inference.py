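"""Derivation of kinship relations from a fact base.

Blood relations (ancestry, siblinghood, aunt/uncle-hood, cousinhood, ...) are
atemporal: once a gamete-origin parenthood fact holds, every relation built
from it holds timelessly.  Spousehood alone is temporal — it is carried by a
marriage bond with an interval, and is queried either at a time point or
"ever".

Naming follows the ontology's relation vocabulary (``natural-parent-of``,
``natural-older-uncle-of``, ``has-spouse`` ...); the Python functions use the
same names with underscores.  Sexed relations read sex as a quality inhering
in the person: a parent bearing the male-sex quality is a natural father.  A
parent bearing both qualities is, by direct evaluation of the definitions,
both a natural father and a natural mother.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import InconsistentFactBaseError, MissingPersonError
from .model import FEMALE, MALE, FactBase, TimePoint

Atom = tuple  # (predicate, *constant args)


@dataclass(frozen=True)
class RelationInstance:
    """One derived relation tuple plus the ground facts supporting it."""

    relation: str
    args: tuple[str, ...]
    support: tuple[Atom, ...] = ()

    def sort_key(self):
        return (self.relation, self.args)


def _require(fb: FactBase, *ids: str) -> None:
    for pid in ids:
        if pid not in fb.persons:
            raise MissingPersonError(f"unknown person id {pid!r}")


def _parent_graph(fb: FactBase) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(fb.persons)
    g.add_edges_from((l.parent, l.child) for l in fb.parent_links)
    return g


def _check_acyclic(fb: FactBase) -> nx.DiGraph:
    g = _parent_graph(fb)
    if not nx.is_directed_acyclic_graph(g):
        raise InconsistentFactBaseError(
            "parent-link graph is cyclic; ancestry is undefined — run validate()"
        )
    return g


# ---------------------------------------------------------------------------
# core relations
# ---------------------------------------------------------------------------


def natural_parent_of(fb: FactBase, x: str, y: str) -> bool:
    """True iff a gamete of x is among those from which y originates."""
    _require(fb, x, y)
    return x in fb.parents_of(y)


def natural_ancestor_of(fb: FactBase, x: str, y: str) -> bool:
    """Recursive ancestry: x reaches y by one or more parent->child steps.

    Atemporal and irreflexive; a cyclic fact base (in which someone would be
    their own ancestor) raises InconsistentFactBaseError.
    """
    _require(fb, x, y)
    g = _check_acyclic(fb)
    return x != y and nx.has_path(g, x, y)


def ancestor_closure(fb: FactBase) -> set[tuple[str, str]]:
    """All (ancestor, descendant) pairs; one graph traversal for bulk use."""
    g = _check_acyclic(fb)
    return {(a, d) for a in fb.persons for d in nx.descendants(g, a)}


def _sexed_parent_of(fb: FactBase, x: str, y: str, sex: str) -> bool:
    return natural_parent_of(fb, x, y) and sex in fb.sexes_of(x)


def natural_father_of(fb: FactBase, x: str, y: str) -> bool:
    """Natural parent in whom a male-sex quality inheres."""
    return _sexed_parent_of(fb, x, y, MALE)


def natural_mother_of(fb: FactBase, x: str, y: str) -> bool:
    """Natural parent in whom a female-sex quality inheres."""
    return _sexed_parent_of(fb, x, y, FEMALE)


def natural_sibling_of(
    fb: FactBase, x: str, y: str, *, full_siblings_only: bool = False
) -> bool:
    """Distinct persons sharing at least one natural parent (half-siblings
    count); with ``full_siblings_only`` both a shared male-sexed and a shared
    female-sexed parent are required.  Symmetric, irreflexive."""
    _require(fb, x, y)
    if x == y:
        return False
    shared = fb.parents_of(x) & fb.parents_of(y)
    if not shared:
        return False
    if not full_siblings_only:
        return True
    return any(MALE in fb.sexes_of(p) for p in shared) and any(
        FEMALE in fb.sexes_of(p) for p in shared
    )


def _linking_parents(fb: FactBase, x: str, y: str) -> frozenset[str]:
    """Parents p of y such that x is a parent of p (grandparent paths)."""
    return frozenset(p for p in fb.parents_of(y) if x in fb.parents_of(p))


def natural_grandparent_of(fb: FactBase, x: str, y: str) -> bool:
    _require(fb, x, y)
    return bool(_linking_parents(fb, x, y))


def natural_maternal_grandparent_of(fb: FactBase, x: str, y: str) -> bool:
    """Grandparent through y's natural mother; the linking parent's sex
    decides the maternal/paternal split, not the grandparent's own sex."""
    _require(fb, x, y)
    return any(FEMALE in fb.sexes_of(p) for p in _linking_parents(fb, x, y))


def natural_paternal_grandparent_of(fb: FactBase, x: str, y: str) -> bool:
    """Grandparent through y's natural father."""
    _require(fb, x, y)
    return any(MALE in fb.sexes_of(p) for p in _linking_parents(fb, x, y))


def _aunt_uncle_links(
    fb: FactBase, x: str, y: str, sex: str, *, full_siblings_only: bool = False
) -> list[str]:
    """Linking parents p of y with x a sex-matching sibling of p."""
    if sex not in fb.sexes_of(x):
        return []
    return sorted(
        p
        for p in fb.parents_of(y)
        if natural_sibling_of(fb, x, p, full_siblings_only=full_siblings_only)
    )


def natural_aunt_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    """Female-sexed natural sibling of a natural parent of y (blood sense
    only — a parent's sibling's spouse is not an aunt here)."""
    _require(fb, x, y)
    return bool(_aunt_uncle_links(fb, x, y, FEMALE, **kw))


def natural_uncle_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    """Male-sexed natural sibling of a natural parent of y."""
    _require(fb, x, y)
    return bool(_aunt_uncle_links(fb, x, y, MALE, **kw))


def _age_ordered_aunt_uncle(
    fb: FactBase, x: str, y: str, sex: str, older: bool, **kw
) -> bool:
    """x is an older (resp. younger) sibling of some linking parent of y.

    Births are compared between x and the *linking parent*; the relation is
    existential over linking parents, and indeterminate (False) whenever the
    relevant birth is unknown.
    """
    _require(fb, x, y)
    bx = fb.persons[x].birth
    if bx is None:
        return False
    for p in _aunt_uncle_links(fb, x, y, sex, **kw):
        bp = fb.persons[p].birth
        if bp is None:
            continue
        if (bx < bp) if older else (bp < bx):
            return True
    return False


def natural_older_aunt_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    return _age_ordered_aunt_uncle(fb, x, y, FEMALE, older=True, **kw)


def natural_younger_aunt_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    return _age_ordered_aunt_uncle(fb, x, y, FEMALE, older=False, **kw)


def natural_older_uncle_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    """An older biological brother of one of y's biological parents."""
    return _age_ordered_aunt_uncle(fb, x, y, MALE, older=True, **kw)


def natural_younger_uncle_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    return _age_ordered_aunt_uncle(fb, x, y, MALE, older=False, **kw)


def _niece_nephew(fb: FactBase, x: str, y: str, sex: str, **kw) -> bool:
    _require(fb, x, y)
    if sex not in fb.sexes_of(x):
        return False
    return any(natural_sibling_of(fb, s, y, **kw) for s in fb.parents_of(x))


def natural_niece_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    """Female-sexed child of a natural sibling of y."""
    return _niece_nephew(fb, x, y, FEMALE, **kw)


def natural_nephew_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    """Male-sexed child of a natural sibling of y."""
    return _niece_nephew(fb, x, y, MALE, **kw)


def natural_first_cousin_of(fb: FactBase, x: str, y: str, **kw) -> bool:
    """Some parent of x and some parent of y are natural siblings, and x, y
    are neither identical nor themselves siblings.  Symmetric."""
    _require(fb, x, y)
    if x == y or natural_sibling_of(fb, x, y, **kw):
        return False
    return any(
        natural_sibling_of(fb, px, py, **kw)
        for px in fb.parents_of(x)
        for py in fb.parents_of(y)
    )


def has_spouse_at(fb: FactBase, x: str, y: str, t: TimePoint) -> bool:
    """True iff a marriage bond over {x, y} has t in its interval.  Symmetric
    and irreflexive: there is no marrying oneself."""
    _require(fb, x, y)
    if x == y:
        return False
    return any(
        b.involves(x) and b.involves(y) and b.interval.contains(t)
        for b in fb.marriage_bonds.values()
    )


def has_spouse_ever(fb: FactBase, x: str, y: str) -> bool:
    """True iff some marriage bond (its interval is non-empty by
    construction) joins x and y."""
    _require(fb, x, y)
    if x == y:
        return False
    return any(b.involves(x) and b.involves(y) for b in fb.marriage_bonds.values())


# ---------------------------------------------------------------------------
# materialization
# ---------------------------------------------------------------------------

#: relation names materialised by infer_all, in the ontology's vocabulary
MATERIALIZED_RELATIONS = (
    "has-natural-child",
    "natural-parent-of",
    "natural-father-of",
    "natural-mother-of",
    "natural-ancestor-of",
    "natural-sibling-of",
    "natural-grandparent-of",
    "natural-maternal-grandparent-of",
    "natural-paternal-grandparent-of",
    "natural-aunt-of",
    "natural-uncle-of",
    "natural-older-aunt-of",
    "natural-younger-aunt-of",
    "natural-older-uncle-of",
    "natural-younger-uncle-of",
    "natural-niece-of",
    "natural-nephew-of",
    "natural-first-cousin-of",
    "has-spouse",
)


def _sex_atom(fb: FactBase, p: str, sex: str) -> Atom:
    return ("sex-quality", p, sex)


def _ancestor_chain(g: nx.DiGraph, x: str, y: str) -> tuple[Atom, ...]:
    path = nx.shortest_path(g, x, y)
    return tuple(("has-natural-child", a, b) for a, b in zip(path, path[1:]))


def _sibling_support(fb: FactBase, x: str, y: str) -> tuple[Atom, ...]:
    p = min(fb.parents_of(x) & fb.parents_of(y))
    return (("has-natural-child", p, x), ("has-natural-child", p, y))


def infer_all(fb: FactBase, *, full_siblings_only: bool = False) -> list[RelationInstance]:
    """Materialise every derivable instance of every supported relation.

    Ground has-natural-child facts are included; symmetric relations appear
    in both argument orders; ``has-spouse`` is the "ever" reading.  Output is
    deterministically sorted by (relation, args).  Raises
    InconsistentFactBaseError on a cyclic parent graph.
    """
    g = _check_acyclic(fb)
    kw = {"full_siblings_only": full_siblings_only}
    out: list[RelationInstance] = []
    people = sorted(fb.persons)

    for l in sorted(fb.parent_links, key=lambda l: (l.parent, l.child)):
        base = ("has-natural-child", l.parent, l.child)
        out.append(RelationInstance(base[0], (l.parent, l.child), (base,)))
        out.append(RelationInstance("natural-parent-of", (l.parent, l.child), (base,)))
        for sex, rel in ((MALE, "natural-father-of"), (FEMALE, "natural-mother-of")):
            if sex in fb.sexes_of(l.parent):
                out.append(
                    RelationInstance(
                        rel, (l.parent, l.child), (base, _sex_atom(fb, l.parent, sex))
                    )
                )

    for a, d in sorted(ancestor_closure(fb)):
        out.append(RelationInstance("natural-ancestor-of", (a, d), _ancestor_chain(g, a, d)))

    pair_relations: list[tuple[str, callable]] = [
        ("natural-sibling-of", lambda x, y: natural_sibling_of(fb, x, y, **kw)),
        ("natural-grandparent-of", lambda x, y: natural_grandparent_of(fb, x, y)),
        (
            "natural-maternal-grandparent-of",
            lambda x, y: natural_maternal_grandparent_of(fb, x, y),
        ),
        (
            "natural-paternal-grandparent-of",
            lambda x, y: natural_paternal_grandparent_of(fb, x, y),
        ),
        ("natural-aunt-of", lambda x, y: natural_aunt_of(fb, x, y, **kw)),
        ("natural-uncle-of", lambda x, y: natural_uncle_of(fb, x, y, **kw)),
        ("natural-older-aunt-of", lambda x, y: natural_older_aunt_of(fb, x, y, **kw)),
        ("natural-younger-aunt-of", lambda x, y: natural_younger_aunt_of(fb, x, y, **kw)),
        ("natural-older-uncle-of", lambda x, y: natural_older_uncle_of(fb, x, y, **kw)),
        ("natural-younger-uncle-of", lambda x, y: natural_younger_uncle_of(fb, x, y, **kw)),
        ("natural-niece-of", lambda x, y: natural_niece_of(fb, x, y, **kw)),
        ("natural-nephew-of", lambda x, y: natural_nephew_of(fb, x, y, **kw)),
        ("natural-first-cousin-of", lambda x, y: natural_first_cousin_of(fb, x, y, **kw)),
    ]
    for x in people:
        for y in people:
            if x == y:
                continue
            for rel, pred in pair_relations:
                if pred(x, y):
                    out.append(RelationInstance(rel, (x, y), _support_for(fb, g, rel, x, y)))

    for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id):
        a, b = bond.partners
        if a == b:
            continue
        atom = ("marriage-bond", bond.id, a, b)
        out.append(RelationInstance("has-spouse", (a, b), (atom,)))
        out.append(RelationInstance("has-spouse", (b, a), (atom,)))

    uniq = {(r.relation, r.args): r for r in out}
    return sorted(uniq.values(), key=RelationInstance.sort_key)


def _support_for(fb: FactBase, g: nx.DiGraph, rel: str, x: str, y: str) -> tuple[Atom, ...]:
    """Minimal witnessing ground facts for one derived pair relation."""
    parent = lambda a, b: ("has-natural-child", a, b)
    if rel == "natural-sibling-of":
        return _sibling_support(fb, x, y)
    if rel.endswith("grandparent-of"):
        links = sorted(_linking_parents(fb, x, y))
        if rel == "natural-maternal-grandparent-of":
            links = [p for p in links if FEMALE in fb.sexes_of(p)]
        elif rel == "natural-paternal-grandparent-of":
            links = [p for p in links if MALE in fb.sexes_of(p)]
        p = links[0]
        sup = (parent(x, p), parent(p, y))
        if rel == "natural-maternal-grandparent-of":
            sup += (_sex_atom(fb, p, FEMALE),)
        elif rel == "natural-paternal-grandparent-of":
            sup += (_sex_atom(fb, p, MALE),)
        return sup
    if "aunt" in rel or "uncle" in rel:
        sex = FEMALE if "aunt" in rel else MALE
        for p in _aunt_uncle_links(fb, x, y, sex):
            bx, bp = fb.persons[x].birth, fb.persons[p].birth
            if "older" in rel and not (bx is not None and bp is not None and bx < bp):
                continue
            if "younger" in rel and not (bx is not None and bp is not None and bp < bx):
                continue
            sup = _sibling_support(fb, x, p) + (parent(p, y), _sex_atom(fb, x, sex))
            if "older" in rel or "younger" in rel:
                sup += (("birth", x, str(bx)), ("birth", p, str(bp)))
            return sup
        raise AssertionError(f"no witness for {rel}({x},{y})")
    if rel in ("natural-niece-of", "natural-nephew-of"):
        sex = FEMALE if rel == "natural-niece-of" else MALE
        s = min(s for s in fb.parents_of(x) if natural_sibling_of(fb, s, y))
        return _sibling_support(fb, s, y) + (parent(s, x), _sex_atom(fb, x, sex))
    if rel == "natural-first-cousin-of":
        for px in sorted(fb.parents_of(x)):
            for py in sorted(fb.parents_of(y)):
                if natural_sibling_of(fb, px, py):
                    return _sibling_support(fb, px, py) + (parent(px, x), parent(py, y))
        raise AssertionError(f"no witness for first-cousin({x},{y})")
    raise AssertionError(f"unhandled relation {rel}")
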