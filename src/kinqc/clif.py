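"""Emission of the kinship ontology as six indexed CLIF modules.

The ontology ships as six Common Logic Interchange Format files:

* ``ancestry.clif`` — the core: replacements of the source kinship axioms
  (subindex ``tkr``), relations requested on the CCA-01 form (``cca``), the
  two-axiom recursive definition of natural ancestry (``nao``), additional
  ordinary kinship relations (``ak``), and links from referenced universals
  to upper-ontology categories (``u``).
* ``cca01-ground.clif`` — the age-ordered aunt/uncle relations peculiar to
  the CCA-01 form (ground truth, but only useful where those relations are
  considered).
* ``ancestry-sct.clif`` / ``sct-ancestry.clif`` — bridge axioms to and from
  SNOMED CT person concepts, generated from the mapping table, one sentence
  per direction.
* ``sct-declarations.clif`` — the particular/class typing axiom plus one
  class declaration per referenced concept; needed whenever a bridge module
  is imported.
* ``unusual.clif`` — exactly the four unusual-situation (alert) axioms.

Each axiom carries a short textual description terminated by an index that is
unique within and across all modules, encoded as a ``cl:comment`` wrapper:
``(cl:comment "description [index|subindex]" <sentence>)``.  An optional
``inspiration.clif`` (the untransformed source axioms) can be emitted for
reference but is not part of the ontology bundle proper.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import sexpr
from .errors import GenerationError, ParseError
from .inference import MATERIALIZED_RELATIONS
from .sct import BOTH, OBJECT, SUBJECT, TO_SCT, SctMapping, default_mappings
from .unusual import DEFAULT_POLICY, CloseRelativePolicy

MODULE_NAMES = (
    "ancestry",
    "cca01-ground",
    "ancestry-sct",
    "sct-ancestry",
    "sct-declarations",
    "unusual",
)


@dataclass(frozen=True)
class ClifAxiom:
    index: str
    subindex: str
    sentence: str  # rendered CLIF s-expression
    comment: str
    module: str

    def render(self) -> str:
        tagged = sexpr.QuotedString(f"{self.comment} [{self.index}|{self.subindex}]")
        return sexpr.render(["cl:comment", tagged, sexpr.parse(self.sentence)[0]])


@dataclass
class OntologyBundle:
    """The six member modules, plus the optional non-member inspiration
    file."""

    modules: dict[str, list[ClifAxiom]]
    inspiration: list[ClifAxiom] | None = None

    def __post_init__(self) -> None:
        if tuple(self.modules) != MODULE_NAMES:
            raise GenerationError(
                f"a bundle has exactly the six modules {MODULE_NAMES}, got {tuple(self.modules)}"
            )

    def all_axioms(self) -> list[ClifAxiom]:
        return [a for name in MODULE_NAMES for a in self.modules[name]]

    def render_module(self, name: str) -> str:
        header = f";; {name}.clif — kinship ontology module ({len(self.modules[name])} axioms)\n"
        if name == "sct-declarations":
            header += ";; import this module whenever a bridge module is imported\n"
        return header + "\n".join(a.render() for a in self.modules[name]) + "\n"

    def render_all(self, *, include_inspiration: bool = False) -> dict[str, str]:
        out = {f"{name}.clif": self.render_module(name) for name in MODULE_NAMES}
        if include_inspiration and self.inspiration is not None:
            text = (
                ";; inspiration.clif — the source kinship axioms, translated to CLIF\n"
                ";; but otherwise untouched.  This file is NOT part of the ontology.\n"
                + "\n".join(a.render() for a in self.inspiration)
                + "\n"
            )
            out["inspiration.clif"] = text
        return out

    def write(self, directory: str | Path, *, include_inspiration: bool = False) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, text in self.render_all(include_inspiration=include_inspiration).items():
            path = directory / name
            path.write_text(text)
            paths.append(path)
        return paths

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for name in MODULE_NAMES:
            h.update(self.render_module(name).encode())
        return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# sentence construction helpers (nested lists -> rendered s-expressions)
# ---------------------------------------------------------------------------


def _forall(vars_: str, body) -> list:
    return ["forall", vars_.split(), body]


def _exists(vars_: str, body) -> list:
    return ["exists", vars_.split(), body]


def _if(a, b) -> list:
    return ["if", a, b]


def _iff(a, b) -> list:
    return ["iff", a, b]


def _and(*parts) -> list:
    return ["and", *parts]


def _or(*parts) -> list:
    return ["or", *parts]


def _not(a) -> list:
    return ["not", a]


def _neq(a: str, b: str) -> list:
    return _not(["=", a, b])


def _atom(pred: str, *args: str) -> list:
    return [pred, *args]


def _sentence(node) -> str:
    return sexpr.render(node)


# ---------------------------------------------------------------------------
# axiom inventories
# ---------------------------------------------------------------------------


def _ancestry_axioms() -> list[tuple[str, str, object]]:
    """(subindex, comment, sentence-tree) for the core module."""
    hnc = _atom
    ax: list[tuple[str, str, object]] = [
        (
            "tkr",
            "no one is their own natural ancestor",
            _forall("x", _not(_atom("natural-ancestor-of", "x", "x"))),
        ),
        (
            "tkr",
            "natural ancestry relates particulars instantiating human-being at some time",
            _forall(
                "x y",
                _if(
                    _atom("natural-ancestor-of", "x", "y"),
                    _and(
                        _exists("t1", _atom("instance-of", "x", "human-being", "t1")),
                        _exists("t2", _atom("instance-of", "y", "human-being", "t2")),
                    ),
                ),
            ),
        ),
        (
            "tkr",
            "no one is married to themselves",
            _forall("x", _not(_atom("has-spouse", "x", "x"))),
        ),
        (
            "tkr",
            "spousehood is symmetric",
            _forall(
                "x y", _if(_atom("has-spouse", "x", "y"), _atom("has-spouse", "y", "x"))
            ),
        ),
        (
            "tkr",
            "spousehood holds exactly when a marriage bond inheres in both partners "
            "at a time at which both exist",
            _forall(
                "x y",
                _iff(
                    _atom("has-spouse", "x", "y"),
                    _and(
                        _neq("x", "y"),
                        _exists(
                            "m t",
                            _and(
                                _atom("instance-of", "m", "marriage-bond", "t"),
                                _atom("inheres-in", "m", "x"),
                                _atom("inheres-in", "m", "y"),
                                _atom("exists-at", "x", "t"),
                                _atom("exists-at", "y", "t"),
                            ),
                        ),
                    ),
                ),
            ),
        ),
        (
            "nao",
            "base case: a natural parent is a natural ancestor",
            _forall(
                "x y",
                _if(hnc("has-natural-child", "x", "y"), _atom("natural-ancestor-of", "x", "y")),
            ),
        ),
        (
            "nao",
            "recursive case: a natural parent of a natural ancestor is a natural ancestor",
            _forall(
                "x y z",
                _if(
                    _and(
                        hnc("has-natural-child", "x", "y"),
                        _atom("natural-ancestor-of", "y", "z"),
                    ),
                    _atom("natural-ancestor-of", "x", "z"),
                ),
            ),
        ),
        (
            "ak",
            "natural parenthood is the inverse reading of has-natural-child",
            _forall(
                "x y",
                _iff(_atom("natural-parent-of", "x", "y"), hnc("has-natural-child", "x", "y")),
            ),
        ),
        (
            "ak",
            "a natural father is a natural parent in whom a male-sex quality inheres",
            _forall(
                "x y",
                _iff(
                    _atom("natural-father-of", "x", "y"),
                    _and(
                        _atom("natural-parent-of", "x", "y"),
                        _exists(
                            "q t",
                            _and(
                                _atom("instance-of", "q", "male-sex", "t"),
                                _atom("inheres-in", "q", "x"),
                            ),
                        ),
                    ),
                ),
            ),
        ),
        (
            "ak",
            "a natural mother is a natural parent in whom a female-sex quality inheres",
            _forall(
                "x y",
                _iff(
                    _atom("natural-mother-of", "x", "y"),
                    _and(
                        _atom("natural-parent-of", "x", "y"),
                        _exists(
                            "q t",
                            _and(
                                _atom("instance-of", "q", "female-sex", "t"),
                                _atom("inheres-in", "q", "x"),
                            ),
                        ),
                    ),
                ),
            ),
        ),
        (
            "ak",
            "natural first cousins: children of natural siblings, themselves neither "
            "identical nor siblings",
            _forall(
                "x y",
                _iff(
                    _atom("natural-first-cousin-of", "x", "y"),
                    _and(
                        _neq("x", "y"),
                        _not(_atom("natural-sibling-of", "x", "y")),
                        _exists(
                            "px py",
                            _and(
                                _atom("has-natural-child", "px", "x"),
                                _atom("has-natural-child", "py", "y"),
                                _atom("natural-sibling-of", "px", "py"),
                            ),
                        ),
                    ),
                ),
            ),
        ),
        (
            "cca",
            "natural siblings share at least one natural parent and are distinct",
            _forall(
                "x y",
                _iff(
                    _atom("natural-sibling-of", "x", "y"),
                    _and(
                        _neq("x", "y"),
                        _exists(
                            "p",
                            _and(
                                _atom("has-natural-child", "p", "x"),
                                _atom("has-natural-child", "p", "y"),
                            ),
                        ),
                    ),
                ),
            ),
        ),
        (
            "cca",
            "a natural grandparent is a natural parent of a natural parent",
            _forall(
                "x y",
                _iff(
                    _atom("natural-grandparent-of", "x", "y"),
                    _exists(
                        "p",
                        _and(
                            _atom("has-natural-child", "x", "p"),
                            _atom("has-natural-child", "p", "y"),
                        ),
                    ),
                ),
            ),
        ),
        (
            "cca",
            "a natural maternal grandparent links through a natural mother of the "
            "grandchild (the linking parent's sex decides)",
            _forall(
                "x y",
                _iff(
                    _atom("natural-maternal-grandparent-of", "x", "y"),
                    _exists(
                        "p",
                        _and(
                            _atom("has-natural-child", "x", "p"),
                            _atom("natural-mother-of", "p", "y"),
                        ),
                    ),
                ),
            ),
        ),
        (
            "cca",
            "a natural paternal grandparent links through a natural father of the "
            "grandchild",
            _forall(
                "x y",
                _iff(
                    _atom("natural-paternal-grandparent-of", "x", "y"),
                    _exists(
                        "p",
                        _and(
                            _atom("has-natural-child", "x", "p"),
                            _atom("natural-father-of", "p", "y"),
                        ),
                    ),
                ),
            ),
        ),
        (
            "cca",
            "a natural aunt is a female-sexed natural sibling of a natural parent",
            _aunt_uncle_tree("natural-aunt-of", "female-sex"),
        ),
        (
            "cca",
            "a natural uncle is a male-sexed natural sibling of a natural parent",
            _aunt_uncle_tree("natural-uncle-of", "male-sex"),
        ),
        (
            "cca",
            "a natural niece is a female-sexed natural child of a natural sibling",
            _niece_nephew_tree("natural-niece-of", "female-sex"),
        ),
        (
            "cca",
            "a natural nephew is a male-sexed natural child of a natural sibling",
            _niece_nephew_tree("natural-nephew-of", "male-sex"),
        ),
        (
            "u",
            "individual-of links particulars to classes; human-being is instantiated "
            "by particulars at times",
            _forall(
                "x t",
                _if(
                    _atom("instance-of", "x", "human-being", "t"),
                    _atom("instance-of", "x", "material-entity", "t"),
                ),
            ),
        ),
        (
            "u",
            "male-sex is a quality universal",
            _forall(
                "q t",
                _if(
                    _atom("instance-of", "q", "male-sex", "t"),
                    _atom("instance-of", "q", "quality", "t"),
                ),
            ),
        ),
        (
            "u",
            "female-sex is a quality universal",
            _forall(
                "q t",
                _if(
                    _atom("instance-of", "q", "female-sex", "t"),
                    _atom("instance-of", "q", "quality", "t"),
                ),
            ),
        ),
        (
            "u",
            "a marriage bond is a relational quality",
            _forall(
                "m t",
                _if(
                    _atom("instance-of", "m", "marriage-bond", "t"),
                    _atom("instance-of", "m", "relational-quality", "t"),
                ),
            ),
        ),
    ]
    return ax


def _aunt_uncle_tree(rel: str, sex: str) -> list:
    return _forall(
        "x y",
        _iff(
            _atom(rel, "x", "y"),
            _exists(
                "p q t",
                _and(
                    _atom("natural-sibling-of", "x", "p"),
                    _atom("has-natural-child", "p", "y"),
                    _atom("instance-of", "q", sex, "t"),
                    _atom("inheres-in", "q", "x"),
                ),
            ),
        ),
    )


def _niece_nephew_tree(rel: str, sex: str) -> list:
    return _forall(
        "x y",
        _iff(
            _atom(rel, "x", "y"),
            _exists(
                "s q t",
                _and(
                    _atom("has-natural-child", "s", "x"),
                    _atom("natural-sibling-of", "s", "y"),
                    _atom("instance-of", "q", sex, "t"),
                    _atom("inheres-in", "q", "x"),
                ),
            ),
        ),
    )


def _cca01_ground_axioms() -> list[tuple[str, str, object]]:
    out = []
    for rel, sex, order, gloss in (
        ("natural-older-aunt-of", "natural-aunt-of", ("x", "p"),
         "an older biological sister of one of one's biological parents"),
        ("natural-younger-aunt-of", "natural-aunt-of", ("p", "x"),
         "a younger biological sister of one of one's biological parents"),
        ("natural-older-uncle-of", "natural-uncle-of", ("x", "p"),
         "an older biological brother of one of one's biological parents"),
        ("natural-younger-uncle-of", "natural-uncle-of", ("p", "x"),
         "a younger biological brother of one of one's biological parents"),
    ):
        out.append(
            (
                "cca",
                gloss,
                _forall(
                    "x y",
                    _iff(
                        _atom(rel, "x", "y"),
                        _and(
                            _atom(sex, "x", "y"),
                            _exists(
                                "p",
                                _and(
                                    _atom("natural-sibling-of", "x", "p"),
                                    _atom("has-natural-child", "p", "y"),
                                    _atom("born-before", *order),
                                ),
                            ),
                        ),
                    ),
                ),
            )
        )
    return out


def _unusual_axioms(policy: CloseRelativePolicy) -> list[tuple[str, str, str, object]]:
    """(kind, subindex, comment, tree); exactly four, one per detector."""
    from .rules import _CLOSE_ATOMS

    disjuncts = []
    for name in sorted(policy.predicates):
        pred = _CLOSE_ATOMS[name]
        disjuncts.append(_atom(pred, "x", "y"))
        disjuncts.append(_atom(pred, "y", "x"))
    close = _or(*disjuncts)
    return [
        (
            "ancestry-loop",
            "unu",
            "a person has a natural child who descends from one of that person's own "
            "natural descendants",
            _forall(
                "x y z",
                _if(
                    _and(
                        _atom("has-natural-child", "x", "y"),
                        _atom("natural-ancestor-of", "x", "z"),
                        _atom("natural-ancestor-of", "z", "y"),
                    ),
                    _atom("occupy-unusual-ancestry-situation", "x", "y", "z"),
                ),
            ),
        ),
        (
            "close-relative-coparents",
            "unu",
            "co-natural-parents of a common person who are close blood relatives "
            "(closeness read symmetrically)",
            _forall(
                "x y z",
                _if(
                    _and(
                        _atom("has-natural-child", "x", "z"),
                        _atom("has-natural-child", "y", "z"),
                        close,
                    ),
                    _atom("occupy-unusual-ancestry-situation", "x", "y", "z"),
                ),
            ),
        ),
        (
            "close-relative-spouses",
            "unu",
            "spouses who are close blood relatives",
            _forall(
                "x y",
                _if(
                    _and(_atom("has-spouse", "x", "y"), close),
                    _atom("occupy-unusual-spousal-situation", "x", "y"),
                ),
            ),
        ),
        (
            "plural-spousal",
            "unu",
            "two contemporaneous marriage bonds of one person to distinct partners",
            _forall(
                "x y z",
                _if(
                    _exists(
                        "t m1 m2",
                        _and(
                            _atom("instance-of", "m1", "marriage-bond", "t"),
                            _atom("instance-of", "m2", "marriage-bond", "t"),
                            _atom("inheres-in", "m1", "x"),
                            _atom("inheres-in", "m1", "y"),
                            _atom("inheres-in", "m2", "x"),
                            _atom("inheres-in", "m2", "z"),
                            _neq("y", "z"),
                        ),
                    ),
                    _atom("occupy-unusual-spousal-situation", "x", "y", "z"),
                ),
            ),
        ),
    ]


#: alert kind of each unusual-module axiom, keyed by position
UNUSUAL_AXIOM_KINDS = (
    "ancestry-loop",
    "close-relative-coparents",
    "close-relative-spouses",
    "plural-spousal",
)


def _inspiration_axioms() -> list[tuple[str, str, object]]:
    """The untransformed source axioms retained for reference (non-member)."""
    return [
        (
            "insp",
            "irreflexivity of ancestry, as in the source ontology",
            _forall("x", _not(_atom("ancestorOf", "x", "x"))),
        ),
        (
            "insp",
            "the rejected child-as-minimal-ancestor axiom (admits counterexamples; "
            "transformed into the ancestry-loop alert axiom)",
            _forall(
                "x y",
                _iff(
                    _atom("hasChild", "x", "y"),
                    _and(
                        _atom("ancestorOf", "x", "y"),
                        _not(
                            _exists(
                                "z",
                                _and(
                                    _atom("ancestorOf", "x", "z"),
                                    _atom("ancestorOf", "z", "y"),
                                ),
                            )
                        ),
                    ),
                ),
            ),
        ),
        (
            "insp",
            "ancestry relates persons, in the source's timeless unary-predicate style",
            _forall(
                "x y",
                _if(
                    _atom("ancestorOf", "x", "y"),
                    _and(_atom("person", "x"), _atom("person", "y")),
                ),
            ),
        ),
    ]


# ---------------------------------------------------------------------------
# bridge-module generation
# ---------------------------------------------------------------------------


def _bridge_to_sct(m: SctMapping) -> object:
    inner = (
        _exists("y", _atom(m.relation, "x", "y"))
        if m.role == SUBJECT
        else _exists("y", _atom(m.relation, "y", "x"))
    )
    return _forall("x", _if(inner, _atom("individual-of", "x", m.concept_fsn)))


def _bridge_from_sct(m: SctMapping) -> object:
    inner = (
        _exists("y", _atom(m.relation, "x", "y"))
        if m.role == SUBJECT
        else _exists("y", _atom(m.relation, "y", "x"))
    )
    return _forall("x", _if(_atom("individual-of", "x", m.concept_fsn), inner))


# ---------------------------------------------------------------------------
# bundle assembly, parsing, counting
# ---------------------------------------------------------------------------

_MODULE_ABBREV = {
    "ancestry": "anc",
    "cca01-ground": "ccg",
    "ancestry-sct": "a2s",
    "sct-ancestry": "s2a",
    "sct-declarations": "dec",
    "unusual": "unu",
}


def build_bundle(
    mappings: Iterable[SctMapping] | None = None,
    policy: CloseRelativePolicy = DEFAULT_POLICY,
    *,
    with_inspiration: bool = True,
) -> OntologyBundle:
    """Assemble the six-module bundle from the axiom inventories and the
    mapping table.  Raises GenerationError if a mapping references a relation
    outside the implemented vocabulary."""
    mappings = list(default_mappings() if mappings is None else mappings)
    for m in mappings:
        if m.relation not in MATERIALIZED_RELATIONS:
            raise GenerationError(
                f"bridge mapping references unimplemented relation {m.relation!r}"
            )

    modules: dict[str, list[ClifAxiom]] = {name: [] for name in MODULE_NAMES}
    counters: dict[str, int] = {}

    def add(module: str, subindex: str, comment: str, tree: object) -> ClifAxiom:
        abbrev = _MODULE_ABBREV[module]
        counters[module] = counters.get(module, 0) + 1
        axiom = ClifAxiom(
            index=f"{abbrev}-{counters[module]:03d}",
            subindex=subindex,
            sentence=_sentence(tree),
            comment=comment,
            module=module,
        )
        modules[module].append(axiom)
        return axiom

    for subindex, comment, tree in _ancestry_axioms():
        add("ancestry", subindex, comment, tree)
    for subindex, comment, tree in _cca01_ground_axioms():
        add("cca01-ground", subindex, comment, tree)
    for _kind, subindex, comment, tree in _unusual_axioms(policy):
        add("unusual", subindex, comment, tree)

    fsns = []
    for m in mappings:
        if m.direction in (TO_SCT, BOTH):
            add(
                "ancestry-sct",
                "bridge",
                f"{m.relation} ({m.role} role) implies membership of {m.concept_fsn}",
                _bridge_to_sct(m),
            )
        if m.direction == BOTH:
            add(
                "sct-ancestry",
                "bridge",
                f"membership of {m.concept_fsn} implies a {m.relation} partner",
                _bridge_from_sct(m),
            )
        if m.concept_fsn not in fsns:
            fsns.append(m.concept_fsn)

    add(
        "sct-declarations",
        "dec",
        "individual-of relates a particular to a class",
        _forall(
            "x y",
            _if(
                _atom("individual-of", "x", "y"),
                _and(_atom("particular", "x"), _atom("class", "y")),
            ),
        ),
    )
    for fsn in fsns:
        add("sct-declarations", "dec", f"{fsn} is a class", _atom("class", fsn))

    bundle = OntologyBundle(modules)
    if with_inspiration:
        insp = []
        for i, (subindex, comment, tree) in enumerate(_inspiration_axioms(), start=1):
            insp.append(
                ClifAxiom(f"insp-{i:03d}", subindex, _sentence(tree), comment, "inspiration")
            )
        bundle.inspiration = insp
    _check_unique_indexes(bundle)
    return bundle


def _check_unique_indexes(bundle: OntologyBundle) -> None:
    seen: set[str] = set()
    for a in bundle.all_axioms():
        if a.index in seen:
            raise GenerationError(f"duplicate axiom index {a.index!r}")
        seen.add(a.index)


def parse_clif(text: str, *, module: str = "") -> list[ClifAxiom]:
    """Parse a CLIF module file back into indexed axioms.

    Forms of shape ``(cl:comment "desc [index|subindex]" sentence)`` recover
    their annotations; bare sentences come back with empty index/comment.
    Malformed input raises ParseError with a character offset.
    """
    out = []
    for form in sexpr.parse(text):
        if not isinstance(form, list) or not form:
            raise ParseError(f"expected a CLIF sentence, got {form!r}")
        index = subindex = comment = ""
        sentence = form
        if form[0] == "cl:comment" and len(form) == 3 and isinstance(form[1], str):
            text_part = str(form[1])
            sentence = form[2]
            if text_part.endswith("]") and "[" in text_part:
                comment, _, tag = text_part.rpartition("[")
                comment = comment.rstrip()
                tag = tag[:-1]
                index, _, subindex = tag.partition("|")
            else:
                comment = text_part
        if not isinstance(sentence, list):
            raise ParseError(f"axiom body must be a compound sentence, got {sentence!r}")
        out.append(ClifAxiom(index, subindex, sexpr.render(sentence), comment, module))
    return out


def count_axioms(bundle: OntologyBundle) -> dict[str, dict]:
    """Per-module totals and per-subindex breakdowns."""
    out: dict[str, dict] = {}
    for name in MODULE_NAMES:
        by_sub: dict[str, int] = {}
        for a in bundle.modules[name]:
            by_sub[a.subindex] = by_sub.get(a.subindex, 0) + 1
        out[name] = {"total": len(bundle.modules[name]), "by_subindex": by_sub}
    return out
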