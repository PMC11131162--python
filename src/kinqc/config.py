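"""Run configuration: which blood relations count as close, how siblinghood
is read, whether plural marriage is alert-worthy, and where the SNOMED CT
mapping table lives.  Loadable from YAML or JSON; validated by pydantic."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .unusual import CLOSE_PREDICATES, CloseRelativePolicy


class Config(BaseModel):
    """Tunable policy knobs.

    ``close_relatives`` defaults to the defining disjunction of the
    close-relative co-parenting axiom; it is meant to be revised to suit a
    data-entry context (widening it trades extra catches for false alarms).
    ``plural_spousal`` disables that alert kind entirely where plural
    marriage is not atypical.  ``full_siblings_only`` narrows siblinghood
    from "shares a parent" to "shares a father and a mother".
    ``time_scale`` optionally pins the expected time scale (tick or date).
    """

    close_relatives: list[str] = Field(default_factory=lambda: sorted(CLOSE_PREDICATES))
    full_siblings_only: bool = False
    plural_spousal: bool = True
    mapping_table: str | None = None
    time_scale: str | None = None

    @field_validator("close_relatives")
    @classmethod
    def _known_predicates(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(CLOSE_PREDICATES)
        if unknown:
            raise ValueError(f"unknown close-relative predicates {sorted(unknown)}")
        if not v:
            raise ValueError("close_relatives must not be empty")
        return v

    @field_validator("time_scale")
    @classmethod
    def _known_scale(cls, v: str | None) -> str | None:
        if v is not None and v not in ("tick", "date"):
            raise ValueError("time_scale must be 'tick' or 'date'")
        return v

    def policy(self) -> CloseRelativePolicy:
        return CloseRelativePolicy(frozenset(self.close_relatives))


def load_config(path: str | Path | None) -> Config:
    if path is None:
        return Config()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return Config.model_validate(data or {})
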