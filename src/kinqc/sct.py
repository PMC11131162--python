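"""Bridging between derived kinship relations and SNOMED CT person concepts.

SNOMED CT models kinship not as relations but as *person* concepts (a
subhierarchy of social entity): sct_Natural-sibling_person,
sct_Niece_person, and so on.  The bridge links a relation instance to a
concept membership ("individual-of") and, for precisely corresponding pairs,
back again.

Directionality is the crux.  Where a relation and a concept precisely
correspond (natural-sibling-of ↔ sct_Natural-sibling_person) the mapping is
bidirectional.  Where the concept only *nearly* corresponds — sct_Niece_person
covers nieces by marriage, so it is wider than natural-niece-of — only the
relation-to-concept direction is sound, and the reverse entailment is never
produced.  Some relations (natural-ancestor-of, natural-older-uncle-of) have
no sufficiently close concept at all and are deliberately unmapped.

The mapping table is data, not code: it ships as a TSV and is expected to
grow as more blood-relative concepts are linked.  Concepts are identified by
fully specified name in the ``sct_Name_person`` convention; the numeric SCTID
column is optional and blank by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable, Union

import pandas as pd

from . import inference as inf
from .errors import ParseError
from .inference import RelationInstance
from .model import FactBase

TO_SCT = "to_sct"
FROM_SCT = "from_sct"
BOTH = "both"
DIRECTIONS = (TO_SCT, FROM_SCT, BOTH)

SUBJECT = "subject"
OBJECT = "object"

Source = Union[str, IO[str]]


@dataclass(frozen=True)
class SctMapping:
    """One relation-to-concept bridge: which argument role of ``relation``
    gains membership of ``concept_fsn``, and in which direction(s) the bridge
    axiom holds."""

    relation: str
    role: str  # subject | object : the argument position that gains the concept
    concept_fsn: str
    direction: str  # to_sct | from_sct | both
    sctid: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.role not in (SUBJECT, OBJECT):
            raise ValueError(f"role must be subject or object, got {self.role!r}")
        if not self.concept_fsn:
            raise ValueError("concept FSN must be non-empty")


@dataclass(frozen=True)
class ConceptAssertion:
    """Membership of a particular (a person) in a SNOMED CT class."""

    particular: str
    concept: str


@dataclass(frozen=True)
class ExistentialClaim:
    """What a concept membership entails about the relation side: there is
    some partner standing in ``relation`` with ``person`` in ``role``."""

    relation: str
    role: str  # role the known person occupies in the relation
    person: str


@dataclass(frozen=True)
class BridgeViolation:
    """An externally supplied concept assertion whose existential claim has
    no witness in the fact base."""

    assertion: ConceptAssertion
    claim: ExistentialClaim
    note: str = ""


def default_mappings() -> list[SctMapping]:
    """The shipped bridge table (data/sct_mappings.tsv).

    Bidirectional rows are the precisely corresponding pairs (child, parent,
    sibling; for has-natural-child the *object* — the child — is the concept
    bearer).  Niece/nephew and maternal/paternal grandparent map one way
    only: the SNOMED concepts include by-marriage readings, so concept
    membership does not entail the blood relation.  natural-ancestor-of and
    the older/younger aunt/uncle relations have no matching concept and are
    absent.
    """
    table = resources.files("kinqc.data").joinpath("sct_mappings.tsv")
    with table.open() as fh:
        return load_mappings(fh)


def lookup(mappings: Iterable[SctMapping], relation: str) -> list[SctMapping]:
    return [m for m in mappings if m.relation == relation]


MAPPING_COLUMNS = ["relation", "role", "concept_fsn", "direction", "sctid"]


def save_mappings(mappings: Iterable[SctMapping], destination: Source) -> None:
    df = pd.DataFrame(
        [
            {
                "relation": m.relation,
                "role": m.role,
                "concept_fsn": m.concept_fsn,
                "direction": m.direction,
                "sctid": m.sctid or "",
            }
            for m in mappings
        ],
        columns=MAPPING_COLUMNS,
    )
    df.to_csv(destination, sep="\t", index=False)


def load_mappings(source: Source) -> list[SctMapping]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns and c != "sctid"]
    if missing:
        raise ParseError(f"mapping table missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                SctMapping(
                    row.relation,
                    row.role,
                    row.concept_fsn,
                    row.direction,
                    (getattr(row, "sctid", "") or None),
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), row=i) from exc
    return out


def _mapped_argument(instance_args: tuple[str, ...], role: str) -> str:
    return instance_args[0] if role == SUBJECT else instance_args[1]


def annotate(
    fb: FactBase,
    relations: Iterable[RelationInstance],
    mappings: Iterable[SctMapping] | None = None,
) -> list[ConceptAssertion]:
    """Relation -> concept direction: for every relation instance and every
    to_sct/both mapping, assert membership of the mapped argument in the
    concept.  Deduplicated and sorted.

    For symmetric relations materialised in both argument orders (sibling),
    a subject-role mapping therefore annotates both ends.
    """
    if mappings is None:
        mappings = default_mappings()
    by_rel: dict[str, list[SctMapping]] = {}
    for m in mappings:
        if m.direction in (TO_SCT, BOTH):
            by_rel.setdefault(m.relation, []).append(m)
    out = set()
    for inst in relations:
        for m in by_rel.get(inst.relation, []):
            out.add(ConceptAssertion(_mapped_argument(inst.args, m.role), m.concept_fsn))
    return sorted(out, key=lambda a: (a.concept, a.particular))


def entail_from_concepts(
    assertions: Iterable[ConceptAssertion],
    mappings: Iterable[SctMapping] | None = None,
) -> list[ExistentialClaim]:
    """Concept -> relation direction: only bidirectional (precisely
    corresponding) mappings entail anything; a membership then yields the
    existential claim that some partner stands in the relation.  to_sct-only
    mappings never produce a reverse entailment."""
    if mappings is None:
        mappings = default_mappings()
    by_concept: dict[str, list[SctMapping]] = {}
    for m in mappings:
        if m.direction in (FROM_SCT, BOTH):
            by_concept.setdefault(m.concept_fsn, []).append(m)
    out = set()
    for a in assertions:
        for m in by_concept.get(a.concept, []):
            out.add(ExistentialClaim(m.relation, m.role, a.particular))
    return sorted(out, key=lambda c: (c.relation, c.role, c.person))


def claim_witnessed(fb: FactBase, claim: ExistentialClaim, *, full_siblings_only: bool = False) -> bool:
    """Does some partner satisfy the claim's relation with the claim's person
    fixed in its role?"""
    pred = _RELATION_PREDICATES.get(claim.relation)
    if pred is None:
        raise ValueError(f"no predicate registered for relation {claim.relation!r}")
    kw = {}
    if claim.relation in _POLICY_SENSITIVE:
        kw["full_siblings_only"] = full_siblings_only
    for other in fb.persons:
        args = (claim.person, other) if claim.role == SUBJECT else (other, claim.person)
        if pred(fb, *args, **kw):
            return True
    return False


_RELATION_PREDICATES = {
    "has-natural-child": inf.natural_parent_of,
    "natural-parent-of": inf.natural_parent_of,
    "natural-father-of": inf.natural_father_of,
    "natural-mother-of": inf.natural_mother_of,
    "natural-sibling-of": inf.natural_sibling_of,
    "natural-niece-of": inf.natural_niece_of,
    "natural-nephew-of": inf.natural_nephew_of,
    "natural-maternal-grandparent-of": inf.natural_maternal_grandparent_of,
    "natural-paternal-grandparent-of": inf.natural_paternal_grandparent_of,
    "natural-first-cousin-of": inf.natural_first_cousin_of,
    "natural-grandparent-of": inf.natural_grandparent_of,
    "natural-aunt-of": inf.natural_aunt_of,
    "natural-uncle-of": inf.natural_uncle_of,
    "has-spouse": inf.has_spouse_ever,
}

_POLICY_SENSITIVE = {
    "natural-sibling-of",
    "natural-niece-of",
    "natural-nephew-of",
    "natural-aunt-of",
    "natural-uncle-of",
    "natural-first-cousin-of",
}


def check_concept_consistency(
    fb: FactBase,
    external_assertions: Iterable[ConceptAssertion],
    mappings: Iterable[SctMapping] | None = None,
) -> list[BridgeViolation]:
    """QC over externally supplied concept memberships: flag any assertion
    under a bidirectional mapping whose existential claim has no witness in
    the fact base.  to_sct-only assertions can never be flagged (the concept
    is wider than the relation, so absence of a blood witness proves
    nothing)."""
    if mappings is None:
        mappings = default_mappings()
    out = []
    for a in sorted(set(external_assertions), key=lambda a: (a.concept, a.particular)):
        for claim in entail_from_concepts([a], mappings):
            if a.particular not in fb.persons or not claim_witnessed(fb, claim):
                out.append(
                    BridgeViolation(
                        a,
                        claim,
                        note=(
                            f"{a.particular} asserted as {a.concept} but no partner "
                            f"witnesses {claim.relation}"
                        ),
                    )
                )
    return out


def load_assertions(source: Source) -> list[ConceptAssertion]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in ("person_id", "concept_fsn"):
        if col not in df.columns:
            raise ParseError(f"assertions table missing column {col!r}")
    return [ConceptAssertion(r.person_id, r.concept_fsn) for r in df.itertuples(index=False)]


def save_assertions(assertions: Iterable[ConceptAssertion], destination: Source) -> None:
    pd.DataFrame(
        [{"person_id": a.particular, "concept_fsn": a.concept} for a in assertions],
        columns=["person_id", "concept_fsn"],
    ).to_csv(destination, sep="\t", index=False)
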