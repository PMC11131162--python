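"""A forward-chaining engine over Kowalski-form Horn rules.

A Kowalski rule is the implication form of a clause: the antecedent conjoins
the atoms of the clause's negative literals, the consequent disjoins its
positive literals.  This engine accepts the Horn fragment (at most one
positive literal); a rule with an empty consequent is an integrity
constraint.  Axioms in the function-free, existential-free fragment — which
is all the kinship and unusual-situation definitions need once existentials
over qualities and bonds are pre-skolemized into ground witness facts — are
compiled with :func:`to_kowalski`, which splits disjunctive antecedents into
one rule per disjunct.

The engine exists as an *independent derivation route*: the procedural
relation functions and the alert detectors are cross-checked against the
least fixpoint of the corresponding rule set over the same ground facts.

Terms are strings; a term beginning with ``?`` is a variable.  Evaluation is
naive bottom-up iteration, which terminates on any finite fact base (no
function symbols, so the Herbrand universe is the constant set).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from . import sexpr
from .errors import ParseError, SafetyError, UnsupportedFragmentError

Atom = tuple  # (predicate, *terms)


def is_variable(term: str) -> bool:
    return isinstance(term, str) and term.startswith("?")


def atom_variables(atom: Atom) -> set[str]:
    return {t for t in atom[1:] if is_variable(t)}


@dataclass(frozen=True)
class KowalskiRule:
    """antecedent atoms -> at most one consequent atom (None = constraint)."""

    antecedent: tuple[Atom, ...]
    consequent: Atom | None

    def check_safe(self) -> None:
        if self.consequent is None:
            return
        body_vars = set().union(*(atom_variables(a) for a in self.antecedent)) if self.antecedent else set()
        free = atom_variables(self.consequent) - body_vars
        if free:
            raise SafetyError(
                f"consequent variables {sorted(free)} do not occur in the antecedent"
            )


# ---------------------------------------------------------------------------
# axiom compilation
# ---------------------------------------------------------------------------

AND = "and"
OR = "or"


def _dnf(expr) -> list[list[Atom]]:
    """Disjunctive normal form of an and/or tree of atoms: a list of
    conjunctions."""
    if isinstance(expr, tuple) and expr and expr[0] not in (AND, OR):
        return [[expr]]
    op, *parts = expr
    if op == OR:
        out = []
        for p in parts:
            out.extend(_dnf(p))
        return out
    if op == AND:
        out = [[]]
        for p in parts:
            out = [conj + alt for conj, alt in product(out, _dnf(p))]
        return out
    raise UnsupportedFragmentError(f"unknown connective {op!r}")


def to_kowalski(body, head: Sequence[Atom] | Atom | None) -> list[KowalskiRule]:
    """Compile an implication ``body -> head`` into Kowalski rules.

    ``body`` is an and/or tree over atoms (no negation, no quantifiers —
    existentials must be pre-skolemized by the caller); ``head`` is a
    disjunction of atoms, a single atom, or None/empty for a constraint.
    Disjunctions in the body split into one rule per resulting clause; a head
    with more than one disjunct is not Horn and raises
    UnsupportedFragmentError.
    """
    if head is None:
        consequent = None
    elif isinstance(head, tuple) and head and not isinstance(head[0], tuple):
        consequent = head
    else:
        head = list(head)
        if len(head) > 1:
            raise UnsupportedFragmentError(
                f"{len(head)} positive literals: outside the Horn fragment"
            )
        consequent = head[0] if head else None
    rules = [KowalskiRule(tuple(conj), consequent) for conj in _dnf(body)]
    for r in rules:
        r.check_safe()
    return rules


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _unify(pattern: Atom, fact: Atom, binding: dict[str, str]) -> dict[str, str] | None:
    if pattern[0] != fact[0] or len(pattern) != len(fact):
        return None
    out = binding
    for p, f in zip(pattern[1:], fact[1:]):
        if is_variable(p):
            bound = out.get(p)
            if bound is None:
                if out is binding:
                    out = dict(binding)
                out[p] = f
            elif bound != f:
                return None
        elif p != f:
            return None
    return out if out is not binding else dict(binding)


class _FactIndex:
    """Facts indexed by predicate and by (predicate, position, constant) so
    body matching can pick selective candidate lists."""

    def __init__(self, facts: Iterable[Atom] = ()):
        self.by_pred: dict[str, list[Atom]] = {}
        self.by_pos: dict[tuple[str, int, str], list[Atom]] = {}
        for f in facts:
            self.add(f)

    def add(self, fact: Atom) -> None:
        self.by_pred.setdefault(fact[0], []).append(fact)
        for pos, val in enumerate(fact[1:]):
            self.by_pos.setdefault((fact[0], pos, val), []).append(fact)

    def candidates(self, pattern: Atom, binding: dict[str, str]) -> list[Atom]:
        """Smallest available candidate list for ``pattern`` given what the
        binding already fixes."""
        best = self.by_pred.get(pattern[0], [])
        for pos, term in enumerate(pattern[1:]):
            val = binding.get(term) if is_variable(term) else term
            if val is not None:
                lst = self.by_pos.get((pattern[0], pos, val), [])
                if len(lst) < len(best):
                    best = lst
        return best


def _match_body(
    body: Sequence[Atom], index: _FactIndex, binding: dict[str, str]
) -> Iterable[dict[str, str]]:
    if not body:
        yield binding
        return
    # greedy join order: expand the atom with the fewest candidates first
    scored = [(len(index.candidates(a, binding)), i) for i, a in enumerate(body)]
    _, pick = min(scored)
    chosen = body[pick]
    rest = [a for i, a in enumerate(body) if i != pick]
    for fact in index.candidates(chosen, binding):
        b2 = _unify(chosen, fact, binding)
        if b2 is not None:
            yield from _match_body(rest, index, b2)


def _substitute(atom: Atom, binding: dict[str, str]) -> Atom:
    return (atom[0], *(binding[t] if is_variable(t) else t for t in atom[1:]))


def fixpoint(
    rules: Iterable[KowalskiRule],
    ground_facts: Iterable[Atom],
    *,
    max_iterations: int | None = None,
) -> set[Atom]:
    """Least fixpoint of the definite rules over the ground facts.

    Naive bottom-up iteration; terminates because the derivable atoms are
    bounded by |predicates| * |constants|^arity.  Constraint rules
    (consequent None) are ignored here — see :func:`check_satisfiable`.
    Raises SafetyError on an unsafe rule.
    """
    definite = []
    for r in rules:
        r.check_safe()
        if r.consequent is not None:
            definite.append(r)
    facts: set[Atom] = set(ground_facts)
    index = _FactIndex(facts)
    iterations = 0
    while True:
        iterations += 1
        if max_iterations is not None and iterations > max_iterations:
            raise RuntimeError("fixpoint iteration bound exceeded")
        new: list[Atom] = []
        for rule in definite:
            for binding in list(_match_body(rule.antecedent, index, {})):
                derived = _substitute(rule.consequent, binding)
                if derived not in facts:
                    facts.add(derived)
                    new.append(derived)
        if not new:
            return facts
        for f in new:
            index.add(f)


def check_satisfiable(
    rules: Iterable[KowalskiRule], ground_facts: Iterable[Atom]
) -> tuple[bool, dict[str, str] | None]:
    """Derive the fixpoint of the definite rules, then test every constraint
    (empty-consequent rule).  Returns (True, None) if no constraint body is
    satisfied, else (False, violating_binding)."""
    rules = list(rules)
    facts = fixpoint(rules, ground_facts)
    index = _FactIndex(facts)
    for rule in rules:
        if rule.consequent is not None:
            continue
        for binding in _match_body(rule.antecedent, index, {}):
            return False, binding
    return True, None


# ---------------------------------------------------------------------------
# textual rule files
# ---------------------------------------------------------------------------
#
# (rule (head ?x ?y) (body-atom-1 ...) (body-atom-2 ...))
# (constraint (body-atom ...) ...)


def _node_to_atom(node) -> Atom:
    if not isinstance(node, list) or not node or any(isinstance(x, list) for x in node):
        raise ParseError(f"expected a flat atom, got {node!r}")
    return tuple(node)


def parse_rules(text: str) -> list[KowalskiRule]:
    out = []
    for form in sexpr.parse(text):
        if not isinstance(form, list) or not form:
            raise ParseError(f"expected (rule ...) or (constraint ...), got {form!r}")
        kind = form[0]
        if kind == "rule":
            if len(form) < 3:
                raise ParseError("a rule needs a head and at least one body atom")
            rule = KowalskiRule(
                tuple(_node_to_atom(n) for n in form[2:]), _node_to_atom(form[1])
            )
        elif kind == "constraint":
            rule = KowalskiRule(tuple(_node_to_atom(n) for n in form[1:]), None)
        else:
            raise ParseError(f"unknown form {kind!r}")
        rule.check_safe()
        out.append(rule)
    return out


def render_rules(rules: Iterable[KowalskiRule]) -> str:
    lines = []
    for r in rules:
        if r.consequent is None:
            lines.append(sexpr.render(["constraint", *[list(a) for a in r.antecedent]]))
        else:
            lines.append(
                sexpr.render(["rule", list(r.consequent), *[list(a) for a in r.antecedent]])
            )
    return "\n".join(lines) + "\n"
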