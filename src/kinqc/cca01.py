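"""The nine family-history relative categories of the CCA-01 enrollment form.

The cholangiocarcinoma screening programme's enrollment form asks whether any
relative was diagnosed with the disease and, if so, which of nine categories
the relative falls in.  The category terms are blood-relation terms (the Thai
originals carry specifically blood senses, even where the English glosses —
"son", "sibling" — do not); spouse (9) is the lone non-blood category and is
evaluated as "ever married", the form giving no date context.

Classification asks: which categories does the pedigree itself support for a
(subject, relative) pair?  Reconciliation then compares a claimed category
against the pedigree-derived set — a cheap but effective QC pass over
questionnaire data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from typing import IO, Union

import pandas as pd

from . import inference as inf
from .errors import MissingPersonError, ParseError
from .model import FactBase

Source = Union[str, IO[str]]


class Cca01Category(IntEnum):
    """The nine relative categories offered by the family-history question."""

    PATERNAL_GRANDPARENT = 1  # paternal grandfather or mother
    MATERNAL_GRANDPARENT = 2  # maternal grandfather or mother
    OLDER_AUNT_OR_UNCLE = 3
    YOUNGER_AUNT_OR_UNCLE = 4
    PARENT = 5  # father or mother
    CHILD = 6  # son or daughter
    SIBLING = 7  # brother or sister
    NEPHEW_OR_NIECE = 8
    SPOUSE = 9

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Cca01Category.PATERNAL_GRANDPARENT: "paternal-grandparent",
    Cca01Category.MATERNAL_GRANDPARENT: "maternal-grandparent",
    Cca01Category.OLDER_AUNT_OR_UNCLE: "older-aunt-or-uncle",
    Cca01Category.YOUNGER_AUNT_OR_UNCLE: "younger-aunt-or-uncle",
    Cca01Category.PARENT: "parent",
    Cca01Category.CHILD: "child",
    Cca01Category.SIBLING: "sibling",
    Cca01Category.NEPHEW_OR_NIECE: "nephew-or-niece",
    Cca01Category.SPOUSE: "spouse",
}


@dataclass(frozen=True)
class FamilyHistoryRecord:
    """One answered family-history line: the relative and the category the
    respondent placed them in."""

    subject: str
    relative: str
    claimed_category: Cca01Category
    diagnosis_flag: bool = True

    def __post_init__(self) -> None:
        if self.subject == self.relative:
            raise ValueError("subject and relative must differ")


def classify(
    fb: FactBase, subject: str, relative: str, *, full_siblings_only: bool = False
) -> set[Cca01Category]:
    """Pedigree-derived categories for (subject, relative).

    The relative occupies the relation's subject position toward the subject:
    category 5 holds iff natural-parent-of(relative, subject), category 6 iff
    the relative is the subject's natural child, and so on.  The set may be
    empty (pedigree lacks any path) or contain several members (which, in a
    consistent pedigree, signals an unusual situation worth inspecting).
    """
    if subject not in fb.persons or relative not in fb.persons:
        raise MissingPersonError(f"unknown person in pair ({subject!r}, {relative!r})")
    kw = {"full_siblings_only": full_siblings_only}
    out: set[Cca01Category] = set()
    if inf.natural_paternal_grandparent_of(fb, relative, subject):
        out.add(Cca01Category.PATERNAL_GRANDPARENT)
    if inf.natural_maternal_grandparent_of(fb, relative, subject):
        out.add(Cca01Category.MATERNAL_GRANDPARENT)
    if inf.natural_older_aunt_of(fb, relative, subject, **kw) or inf.natural_older_uncle_of(
        fb, relative, subject, **kw
    ):
        out.add(Cca01Category.OLDER_AUNT_OR_UNCLE)
    if inf.natural_younger_aunt_of(fb, relative, subject, **kw) or inf.natural_younger_uncle_of(
        fb, relative, subject, **kw
    ):
        out.add(Cca01Category.YOUNGER_AUNT_OR_UNCLE)
    if inf.natural_parent_of(fb, relative, subject):
        out.add(Cca01Category.PARENT)
    if inf.natural_parent_of(fb, subject, relative):
        out.add(Cca01Category.CHILD)
    if inf.natural_sibling_of(fb, relative, subject, **kw):
        out.add(Cca01Category.SIBLING)
    if inf.natural_niece_of(fb, relative, subject, **kw) or inf.natural_nephew_of(
        fb, relative, subject, **kw
    ):
        out.add(Cca01Category.NEPHEW_OR_NIECE)
    if inf.has_spouse_ever(fb, subject, relative):
        out.add(Cca01Category.SPOUSE)
    return out


CONFIRMED = "confirmed"
CONTRADICTED = "contradicted"
UNVERIFIABLE = "unverifiable"
INDETERMINATE_AGE = "indeterminate-age"


@dataclass(frozen=True)
class RecordFinding:
    record: FamilyHistoryRecord
    status: str  # confirmed | contradicted | unverifiable | indeterminate-age
    derived_categories: frozenset[Cca01Category]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "subject": self.record.subject,
            "relative": self.record.relative,
            "claimed_category": int(self.record.claimed_category),
            "status": self.status,
            "derived_categories": sorted(int(c) for c in self.derived_categories),
            "note": self.note,
        }


def reconcile(
    fb: FactBase,
    records: list[FamilyHistoryRecord],
    *,
    full_siblings_only: bool = False,
) -> list[RecordFinding]:
    """Compare each claimed category against the pedigree-derived set.

    Statuses: *confirmed* (claimed among derived), *indeterminate-age*
    (claimed older/younger aunt-uncle, the base aunt/uncle relation holds but
    a missing birth leaves the age order open), *contradicted* (pedigree
    supports other categories but not the claimed one), *unverifiable*
    (pedigree supports no category for the pair at all).
    """
    kw = {"full_siblings_only": full_siblings_only}
    out = []
    for rec in records:
        derived = classify(fb, rec.subject, rec.relative, **kw)
        claimed = rec.claimed_category
        if claimed in derived:
            status, note = CONFIRMED, ""
        elif claimed in (
            Cca01Category.OLDER_AUNT_OR_UNCLE,
            Cca01Category.YOUNGER_AUNT_OR_UNCLE,
        ) and (
            inf.natural_aunt_of(fb, rec.relative, rec.subject, **kw)
            or inf.natural_uncle_of(fb, rec.relative, rec.subject, **kw)
        ) and not (
            Cca01Category.OLDER_AUNT_OR_UNCLE in derived
            or Cca01Category.YOUNGER_AUNT_OR_UNCLE in derived
        ):
            status = INDETERMINATE_AGE
            note = "aunt/uncle relation holds but a missing birth leaves the age order open"
        elif derived:
            status = CONTRADICTED
            note = f"pedigree supports {sorted(int(c) for c in derived)} instead"
        else:
            status, note = UNVERIFIABLE, "pedigree derives no category for this pair"
        out.append(RecordFinding(rec, status, frozenset(derived), note))
    return out


RECORD_COLUMNS = ["subject_id", "relative_id", "category_code", "diagnosis"]


def load_records(source: Source) -> list[FamilyHistoryRecord]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"records table missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            code = Cca01Category(int(row.category_code))
        except ValueError as exc:
            raise ParseError(f"invalid category code {row.category_code!r}", row=i) from exc
        flag = str(row.diagnosis).strip().lower() in ("1", "true", "yes", "y")
        try:
            out.append(FamilyHistoryRecord(row.subject_id, row.relative_id, code, flag))
        except ValueError as exc:
            raise ParseError(str(exc), row=i) from exc
    return out


def findings_to_json(findings: list[RecordFinding], indent: int = 2) -> str:
    return json.dumps([f.to_dict() for f in findings], indent=indent)


def findings_to_tsv(findings: list[RecordFinding]) -> str:
    lines = ["subject_id\trelative_id\tclaimed\tstatus\tderived\tnote"]
    for f in findings:
        derived = ",".join(str(int(c)) for c in sorted(f.derived_categories))
        lines.append(
            f"{f.record.subject}\t{f.record.relative}\t{int(f.record.claimed_category)}"
            f"\t{f.status}\t{derived}\t{f.note}"
        )
    return "\n".join(lines) + "\n"
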