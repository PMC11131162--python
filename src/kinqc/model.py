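"""Domain model for pedigrees: persons, time, sex qualities, parent links,
marriage bonds, and the fact base with its integrity checks.

The model follows a realist reading of kinship: parenthood is gamete-origin
("natural") parenthood, sex is a quality inhering in a person, and marriage is
a bond between two persons carrying a temporal extent.  Blood relations are
atemporal; only spousehood is evaluated against time.  The fact base is
deliberately permissive — it can *hold* inconsistent data (a self-parent, a
self-spouse, a parental cycle) so that :func:`validate` can report the problem
as data rather than crash on load.

Time points are either ISO calendar dates or signed integer ticks; the two
scales never mix within one fact base.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import pandas as pd

from .errors import MissingPersonError, ParseError, TimeScaleError

MISSING_PARENT = "0"
MISSING_VALUE = "."

MALE = "male-sex"
FEMALE = "female-sex"
SEX_CODES = {"1": MALE, "2": FEMALE}
SEX_TO_CODE = {MALE: "1", FEMALE: "2"}

_TICK_RE = re.compile(r"^[+-]?\d+$")

TimeValue = Union[int, _dt.date]


@dataclass(frozen=True, order=False)
class TimePoint:
    """A point on a single time scale: a calendar date or an integer tick."""

    value: TimeValue

    @property
    def scale(self) -> str:
        return "tick" if isinstance(self.value, int) else "date"

    def _check(self, other: "TimePoint") -> None:
        if not isinstance(other, TimePoint):
            raise TypeError(f"cannot compare TimePoint with {type(other).__name__}")
        if self.scale != other.scale:
            raise TimeScaleError(
                f"cannot compare a {self.scale} time point with a {other.scale} one"
            )

    def __lt__(self, other: "TimePoint") -> bool:
        self._check(other)
        return self.value < other.value

    def __le__(self, other: "TimePoint") -> bool:
        self._check(other)
        return self.value <= other.value

    def __gt__(self, other: "TimePoint") -> bool:
        return not self.__le__(other)

    def __ge__(self, other: "TimePoint") -> bool:
        return not self.__lt__(other)

    def __str__(self) -> str:
        return self.value.isoformat() if self.scale == "date" else str(self.value)


def parse_timepoint(text: str) -> TimePoint | None:
    """Parse ``text`` into a TimePoint; ``.``/empty mean unknown (None)."""
    text = text.strip()
    if text in ("", MISSING_VALUE):
        return None
    if _TICK_RE.match(text):
        return TimePoint(int(text))
    try:
        return TimePoint(_dt.date.fromisoformat(text))
    except ValueError as exc:
        raise ParseError(f"unparseable time point {text!r}") from exc


@dataclass(frozen=True)
class TimeInterval:
    """Half-open interval [start, end); an absent end means open-ended."""

    start: TimePoint
    end: TimePoint | None = None

    def __post_init__(self) -> None:
        if self.end is not None and not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")

    def contains(self, t: TimePoint) -> bool:
        return self.start <= t and (self.end is None or t < self.end)

    def overlaps(self, other: "TimeInterval") -> bool:
        """True iff the half-open intervals share at least one time point."""
        if self.end is not None and not other.start < self.end:
            return False
        if other.end is not None and not self.start < other.end:
            return False
        return True


@dataclass(frozen=True)
class Person:
    id: str
    birth: TimePoint | None = None
    death: TimePoint | None = None

    def __post_init__(self) -> None:
        if self.birth is not None and self.death is not None and not self.birth < self.death:
            raise ValueError(f"person {self.id}: birth {self.birth} not before death {self.death}")


@dataclass(frozen=True)
class SexQuality:
    """A sex quality inhering in a person.

    A bearer may carry both values at once (the simultaneous-hermaphrodite
    reading); each value is asserted at most once per bearer.
    """

    bearer: str
    value: str

    def __post_init__(self) -> None:
        if self.value not in (MALE, FEMALE):
            raise ValueError(f"unknown sex quality value {self.value!r}")


@dataclass(frozen=True)
class ParentLink:
    """Gamete-origin parenthood: a gamete of ``parent`` is among those from
    which ``child`` originates."""

    parent: str
    child: str


@dataclass(frozen=True)
class MarriageBond:
    """A relational quality inhering in exactly two persons, with the
    temporal extent of the spousehood it carries."""

    id: str
    partners: tuple[str, str]
    interval: TimeInterval

    def __post_init__(self) -> None:
        # normalise the unordered pair for stable equality/hashing
        a, b = self.partners
        if b < a:
            object.__setattr__(self, "partners", (b, a))

    def involves(self, person: str) -> bool:
        return person in self.partners

    def other(self, person: str) -> str:
        a, b = self.partners
        return b if person == a else a


@dataclass(frozen=True)
class IntegrityViolation:
    """A consistency problem found in a fact base; data, not an exception."""

    kind: str  # self-parent | parental-cycle | self-spouse |
    #            duplicate-sexed-parent | bond-outside-lifespan
    participants: tuple[str, ...]
    note: str = ""


class FactBase:
    """Ground kinship assertions about one pedigree namespace.

    Every id referenced by a link, bond or quality must name a registered
    person (enforced on insertion); logical consistency (acyclicity,
    irreflexivity, one sexed parent per sex) is *checked*, not enforced —
    see :func:`validate`.
    """

    def __init__(self) -> None:
        self.persons: dict[str, Person] = {}
        self.sex_qualities: set[SexQuality] = set()
        self.parent_links: set[ParentLink] = set()
        self.marriage_bonds: dict[str, MarriageBond] = {}
        self._time_scale: str | None = None

    # -- registration ------------------------------------------------------

    def _register_time(self, t: TimePoint | None) -> None:
        if t is None:
            return
        if self._time_scale is None:
            self._time_scale = t.scale
        elif self._time_scale != t.scale:
            raise TimeScaleError(
                f"fact base uses {self._time_scale} times; got a {t.scale} value"
            )

    def add_person(self, person: Person) -> None:
        if person.id in self.persons:
            raise ValueError(f"duplicate person id {person.id!r}")
        self._register_time(person.birth)
        self._register_time(person.death)
        self.persons[person.id] = person

    def _require(self, *ids: str) -> None:
        for pid in ids:
            if pid not in self.persons:
                raise MissingPersonError(f"unknown person id {pid!r}")

    def add_sex_quality(self, quality: SexQuality) -> None:
        self._require(quality.bearer)
        self.sex_qualities.add(quality)

    def add_parent_link(self, link: ParentLink) -> None:
        self._require(link.parent, link.child)
        self.parent_links.add(link)

    def add_marriage_bond(self, bond: MarriageBond) -> None:
        self._require(*set(bond.partners))
        if bond.id in self.marriage_bonds:
            raise ValueError(f"duplicate bond id {bond.id!r}")
        self._register_time(bond.interval.start)
        if bond.interval.end is not None:
            self._register_time(bond.interval.end)
        self.marriage_bonds[bond.id] = bond

    # -- convenience views -------------------------------------------------

    def sexes_of(self, person: str) -> frozenset[str]:
        return frozenset(q.value for q in self.sex_qualities if q.bearer == person)

    def parents_of(self, child: str) -> frozenset[str]:
        return frozenset(l.parent for l in self.parent_links if l.child == child)

    def children_of(self, parent: str) -> frozenset[str]:
        return frozenset(l.child for l in self.parent_links if l.parent == parent)

    def bonds_of(self, person: str) -> list[MarriageBond]:
        return [b for b in self.marriage_bonds.values() if b.involves(person)]

    def copy(self) -> "FactBase":
        """Independent copy (the contained records are immutable and shared)."""
        fb = FactBase()
        fb.persons = dict(self.persons)
        fb.sex_qualities = set(self.sex_qualities)
        fb.parent_links = set(self.parent_links)
        fb.marriage_bonds = dict(self.marriage_bonds)
        fb._time_scale = self._time_scale
        return fb

    # -- equality (order-insensitive) --------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FactBase):
            return NotImplemented
        return (
            self.persons == other.persons
            and self.sex_qualities == other.sex_qualities
            and self.parent_links == other.parent_links
            and self.marriage_bonds == other.marriage_bonds
        )

    def __repr__(self) -> str:
        return (
            f"FactBase(persons={len(self.persons)}, links={len(self.parent_links)}, "
            f"bonds={len(self.marriage_bonds)})"
        )


def exists_at(person: Person, t: TimePoint) -> bool:
    """Half-open lifespan check [birth, death); unknown bounds are permissive
    (an unknown birth or death never makes this false)."""
    if person.birth is not None and t < person.birth:
        return False
    if person.death is not None and person.death <= t:
        return False
    return True


# ---------------------------------------------------------------------------
# integrity checking
# ---------------------------------------------------------------------------


def _parental_cycles(fb: FactBase) -> list[tuple[str, ...]]:
    """Strongly-connected components of size > 1 in the parent->child graph
    (self-loops are reported separately as self-parent)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(fb.persons)
    g.add_edges_from((l.parent, l.child) for l in fb.parent_links if l.parent != l.child)
    return [tuple(sorted(c)) for c in nx.strongly_connected_components(g) if len(c) > 1]


def validate(fb: FactBase) -> list[IntegrityViolation]:
    """Check hard integrity constraints; an empty list means consistent.

    Violation kinds: self-parent, parental-cycle (a person would be its own
    ancestor), self-spouse, duplicate-sexed-parent (two distinct male-sexed
    or two distinct female-sexed parents of one child), bond-outside-lifespan
    (a bond starting before a partner's known birth or at/after a partner's
    known death).
    """
    out: list[IntegrityViolation] = []
    for link in sorted(fb.parent_links, key=lambda l: (l.parent, l.child)):
        if link.parent == link.child:
            out.append(IntegrityViolation("self-parent", (link.parent,)))
    for cycle in sorted(_parental_cycles(fb)):
        out.append(
            IntegrityViolation(
                "parental-cycle", cycle, note="these persons would be their own ancestors"
            )
        )
    for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id):
        a, b = bond.partners
        if a == b:
            out.append(IntegrityViolation("self-spouse", (a,), note=f"bond {bond.id}"))
            continue
        for pid in (a, b):
            person = fb.persons[pid]
            start = bond.interval.start
            if (person.birth is not None and start < person.birth) or (
                person.death is not None and person.death <= start
            ):
                out.append(
                    IntegrityViolation(
                        "bond-outside-lifespan",
                        (pid,),
                        note=f"bond {bond.id} starts outside the lifespan of {pid}",
                    )
                )
    children = sorted({l.child for l in fb.parent_links})
    for child in children:
        parents = fb.parents_of(child)
        for sex in (MALE, FEMALE):
            sexed = sorted(p for p in parents if sex in fb.sexes_of(p))
            if len(sexed) > 1:
                out.append(
                    IntegrityViolation(
                        "duplicate-sexed-parent",
                        (child, *sexed),
                        note=f"{len(sexed)} {sex} parents of {child}",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

PEDIGREE_COLUMNS = ["person_id", "father_id", "mother_id", "sex", "birth", "death"]
UNIONS_COLUMNS = ["bond_id", "partner_a", "partner_b", "start", "end"]

Source = Union[str, IO[str]]


def _read_table(source: Source, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}; expected {columns}")
    return df


def load_pedigree(pedigree: Source, unions: Source | None = None) -> FactBase:
    """Build a FactBase from a pedigree table and an optional unions table.

    Pedigree columns: person_id father_id mother_id sex birth death, with
    ``0`` as the missing-parent sentinel (PED/FAM convention), sex coded
    1=male-sex / 2=female-sex / 0=unknown, and ``.`` for unknown dates.
    Unions columns: bond_id partner_a partner_b start end (``.`` = open end).
    """
    fb = FactBase()
    ped = _read_table(pedigree, PEDIGREE_COLUMNS)
    rows = list(ped.itertuples(index=False))
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        pid = str(row.person_id).strip()
        if not pid or pid == MISSING_PARENT:
            raise ParseError(f"invalid person id {pid!r}", row=i)
        if str(row.sex).strip() not in ("0", "1", "2"):
            raise ParseError(f"invalid sex code {row.sex!r} for {pid}", row=i)
        try:
            person = Person(pid, parse_timepoint(str(row.birth)), parse_timepoint(str(row.death)))
        except (ParseError, ValueError) as exc:
            raise ParseError(f"bad row for {pid}: {exc}", row=i) from exc
        fb.add_person(person)
        sex = SEX_CODES.get(str(row.sex).strip())
        if sex is not None:
            fb.add_sex_quality(SexQuality(pid, sex))
    for i, row in enumerate(rows, start=2):
        child = str(row.person_id).strip()
        for parent in (str(row.father_id).strip(), str(row.mother_id).strip()):
            if parent in ("", MISSING_PARENT, MISSING_VALUE):
                continue
            if parent not in fb.persons:
                raise MissingPersonError(
                    f"row {i}: parent {parent!r} of {child!r} is not a registered person"
                )
            fb.add_parent_link(ParentLink(parent, child))
    if unions is not None:
        uni = _read_table(unions, UNIONS_COLUMNS)
        for i, row in enumerate(uni.itertuples(index=False), start=2):
            a, b = str(row.partner_a).strip(), str(row.partner_b).strip()
            for pid in (a, b):
                if pid not in fb.persons:
                    raise MissingPersonError(f"row {i}: bond partner {pid!r} is unregistered")
            start = parse_timepoint(str(row.start))
            if start is None:
                raise ParseError(f"bond {row.bond_id}: start time is required", row=i)
            try:
                interval = TimeInterval(start, parse_timepoint(str(row.end)))
            except ValueError as exc:
                raise ParseError(f"bond {row.bond_id}: {exc}", row=i) from exc
            fb.add_marriage_bond(MarriageBond(str(row.bond_id).strip(), (a, b), interval))
    return fb


def _fmt_time(t: TimePoint | None) -> str:
    return MISSING_VALUE if t is None else str(t)


def factbase_frames(fb: FactBase) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a fact base as (pedigree, unions) data frames in the tabular
    dialect of :func:`load_pedigree`."""
    ped_rows = []
    for pid in sorted(fb.persons):
        person = fb.persons[pid]
        sexes = fb.sexes_of(pid)
        if len(sexes) > 1:
            raise ValueError(
                f"person {pid} bears both sex qualities; the tabular dialect cannot "
                "encode this — use the JSON serialization instead"
            )
        fathers = sorted(p for p in fb.parents_of(pid) if MALE in fb.sexes_of(p))
        mothers = sorted(p for p in fb.parents_of(pid) if FEMALE in fb.sexes_of(p))
        unsexed = sorted(
            p for p in fb.parents_of(pid) if not fb.sexes_of(p)
        )
        if len(fathers) > 1 or len(mothers) > 1 or (len(fathers) + len(mothers) + len(unsexed)) > 2:
            raise ValueError(
                f"person {pid}: parent set not expressible as father/mother columns"
            )
        # an unsexed parent goes in whichever column is free (father first)
        spare = list(unsexed)
        father = fathers[0] if fathers else (spare.pop(0) if spare else MISSING_PARENT)
        mother = mothers[0] if mothers else (spare.pop(0) if spare else MISSING_PARENT)
        ped_rows.append(
            {
                "person_id": pid,
                "father_id": father,
                "mother_id": mother,
                "sex": SEX_TO_CODE[next(iter(sexes))] if sexes else "0",
                "birth": _fmt_time(person.birth),
                "death": _fmt_time(person.death),
            }
        )
    uni_rows = [
        {
            "bond_id": bond.id,
            "partner_a": bond.partners[0],
            "partner_b": bond.partners[1],
            "start": _fmt_time(bond.interval.start),
            "end": _fmt_time(bond.interval.end),
        }
        for bond in sorted(fb.marriage_bonds.values(), key=lambda b: b.id)
    ]
    return (
        pd.DataFrame(ped_rows, columns=PEDIGREE_COLUMNS),
        pd.DataFrame(uni_rows, columns=UNIONS_COLUMNS),
    )


def write_factbase(fb: FactBase, pedigree: Source, unions: Source | None = None) -> None:
    """Write the tabular form; round-trips with :func:`load_pedigree` up to
    row ordering.  ``unions`` may be omitted only for a bond-free fact base."""
    ped_df, uni_df = factbase_frames(fb)
    ped_df.to_csv(pedigree, sep="\t", index=False)
    if unions is not None:
        uni_df.to_csv(unions, sep="\t", index=False)
    elif len(uni_df):
        raise ValueError("fact base has marriage bonds; a unions destination is required")


# ---------------------------------------------------------------------------
# JSON serialization (lossless: can carry both-sex bearers and any parent set)
# ---------------------------------------------------------------------------

FACTBASE_JSON_SCHEMA: dict = {
    "$id": "kinqc/factbase.schema.json",
    "type": "object",
    "required": ["persons", "sex_qualities", "parent_links", "marriage_bonds"],
    "properties": {
        "persons": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id"],
                "properties": {
                    "id": {"type": "string"},
                    "birth": {"type": ["string", "null"]},
                    "death": {"type": ["string", "null"]},
                },
            },
        },
        "sex_qualities": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["bearer", "value"],
                "properties": {
                    "bearer": {"type": "string"},
                    "value": {"enum": [MALE, FEMALE]},
                },
            },
        },
        "parent_links": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["parent", "child"],
                "properties": {"parent": {"type": "string"}, "child": {"type": "string"}},
            },
        },
        "marriage_bonds": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id", "partners", "start"],
                "properties": {
                    "id": {"type": "string"},
                    "partners": {"type": "array", "minItems": 2, "maxItems": 2},
                    "start": {"type": "string"},
                    "end": {"type": ["string", "null"]},
                },
            },
        },
    },
}


def factbase_to_dict(fb: FactBase) -> dict:
    return {
        "persons": [
            {"id": p.id, "birth": _none_or_str(p.birth), "death": _none_or_str(p.death)}
            for p in sorted(fb.persons.values(), key=lambda p: p.id)
        ],
        "sex_qualities": [
            {"bearer": q.bearer, "value": q.value}
            for q in sorted(fb.sex_qualities, key=lambda q: (q.bearer, q.value))
        ],
        "parent_links": [
            {"parent": l.parent, "child": l.child}
            for l in sorted(fb.parent_links, key=lambda l: (l.parent, l.child))
        ],
        "marriage_bonds": [
            {
                "id": b.id,
                "partners": list(b.partners),
                "start": str(b.interval.start),
                "end": _none_or_str(b.interval.end),
            }
            for b in sorted(fb.marriage_bonds.values(), key=lambda b: b.id)
        ],
    }


def _none_or_str(t: TimePoint | None) -> str | None:
    return None if t is None else str(t)


def _opt_time(text: str | None) -> TimePoint | None:
    return None if text is None else parse_timepoint(text)


def check_factbase_dict(data: dict) -> None:
    """Light structural validation against FACTBASE_JSON_SCHEMA's shape."""
    if not isinstance(data, dict):
        raise ParseError("fact base JSON must be an object")
    for key in ("persons", "sex_qualities", "parent_links", "marriage_bonds"):
        if not isinstance(data.get(key), list):
            raise ParseError(f"fact base JSON: {key!r} must be a list")


def factbase_from_dict(data: dict) -> FactBase:
    check_factbase_dict(data)
    fb = FactBase()
    for p in data["persons"]:
        fb.add_person(Person(p["id"], _opt_time(p.get("birth")), _opt_time(p.get("death"))))
    for q in data["sex_qualities"]:
        fb.add_sex_quality(SexQuality(q["bearer"], q["value"]))
    for l in data["parent_links"]:
        fb.add_parent_link(ParentLink(l["parent"], l["child"]))
    for b in data["marriage_bonds"]:
        start = parse_timepoint(b["start"])
        assert start is not None
        fb.add_marriage_bond(
            MarriageBond(b["id"], tuple(b["partners"]), TimeInterval(start, _opt_time(b.get("end"))))
        )
    return fb


def save_factbase_json(fb: FactBase, destination: Source) -> None:
    payload = json.dumps(factbase_to_dict(fb), indent=2)
    if hasattr(destination, "write"):
        destination.write(payload)
    else:
        with open(destination, "w") as fh:
            fh.write(payload)


def load_factbase_json(source: Source) -> FactBase:
    if hasattr(source, "read"):
        data = json.load(source)
    else:
        with open(source) as fh:
            data = json.load(fh)
    return factbase_from_dict(data)
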