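"""Domain types shared by every pipeline stage.

The package models three kinds of hospital-EHR records (demographics,
ICD-10 claims, free-text clinical notes), the per-patient evidence each
extraction engine produces, and the cohort assignments the fusion step
derives from that evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class DiagnosisPosition(str, Enum):
    """Position of an ICD-10 code within a hospital stay (French PMSI)."""

    PRIMARY = "primary"
    RELATED = "related"
    ASSOCIATED = "associated"


class NoteType(str, Enum):
    PATHOLOGY_REPORT = "pathology_report"
    MDM_REPORT = "mdm_report"


class Source(str, Enum):
    """The three evidence sources the multimodal algorithm fuses."""

    ICD10 = "ICD10"
    ADICAP = "ADICAP"
    NLP = "NLP"


class Flavour(str, Enum):
    """The two rarity axes of the REFCOR rare-HNC definition."""

    RARE_TOPOGRAPHY = "rare_topography"
    RARE_HISTOLOGY = "rare_histology"


ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code to dot-free uppercase ("C30.0" -> "C300")."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class Person:
    person_id: str
    birth_year: Optional[int] = None
    sex: Sex = Sex.UNKNOWN


@dataclass(frozen=True)
class ClaimRecord:
    """One ICD-10 diagnosis assignment for a patient stay."""

    person_id: str
    icd10_code: str
    diagnosis_position: DiagnosisPosition
    claim_date: Optional[str] = None

    def __post_init__(self) -> None:
        if not ICD10_PATTERN.match(self.icd10_code):
            raise ValueError(
                f"malformed ICD-10 code {self.icd10_code!r} "
                f"(expected dot-free uppercase, e.g. 'C301')"
            )


@dataclass(frozen=True)
class ClinicalNote:
    """One pathology or multidisciplinary-meeting (MDM) report."""

    note_id: str
    person_id: str
    note_type: NoteType
    text: str
    note_date: Optional[str] = None


@dataclass
class Dataset:
    """Validated container for one EHR extract.

    Referential integrity (every claim/note points at a known person) is
    enforced at construction time.
    """

    persons: list[Person]
    claims: list[ClaimRecord]
    notes: list[ClinicalNote]

    def __post_init__(self) -> None:
        ids = [p.person_id for p in self.persons]
        known = set(ids)
        if len(ids) != len(known):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate person_id(s): {dupes}")
        note_ids = [n.note_id for n in self.notes]
        if len(note_ids) != len(set(note_ids)):
            dupes = sorted({i for i in note_ids if note_ids.count(i) > 1})
            raise IntegrityError(f"duplicate note_id(s): {dupes}")
        orphans = sorted(
            {r.person_id for r in (*self.claims, *self.notes) if r.person_id not in known}
        )
        if orphans:
            raise IntegrityError(
                f"claims/notes reference unknown person_id(s): {orphans}"
            )
        # per-person indexes; the container is treated as immutable after
        # construction
        self._claims_by: dict[str, list[ClaimRecord]] = {}
        for c in self.claims:
            self._claims_by.setdefault(c.person_id, []).append(c)
        self._path_notes_by: dict[str, list[ClinicalNote]] = {}
        for n in self.notes:
            if n.note_type is NoteType.PATHOLOGY_REPORT:
                self._path_notes_by.setdefault(n.person_id, []).append(n)

    def claims_of(self, person_id: str) -> list[ClaimRecord]:
        return list(self._claims_by.get(person_id, ()))

    def pathology_notes_of(self, person_id: str) -> list[ClinicalNote]:
        return list(self._path_notes_by.get(person_id, ()))


class IntegrityError(ValueError):
    """A dataset violates referential integrity or uniqueness invariants."""


class SchemaError(ValueError):
    """A table file lacks a mandatory column."""


@dataclass(frozen=True)
class GoldLabel:
    """Expert annotation of one patient's true rare-HNC status."""

    person_id: str
    is_rare_topography: bool
    is_rare_histology: bool

    @property
    def is_rare_hnc(self) -> bool:
        return self.is_rare_topography or self.is_rare_histology


@dataclass(frozen=True)
class SourceEvidence:
    """One (patient, source, rarity-flavour) finding with its provenance.

    Provenance is either the triggering ICD-10 claim rendered as a string
    ("C300@primary") or a (note_id, start, end) span into the note text.
    """

    person_id: str
    source: Source
    flavour: Flavour
    provenance: str

    def __post_init__(self) -> None:
        if self.source is Source.ICD10 and self.flavour is not Flavour.RARE_TOPOGRAPHY:
            raise ValueError("ICD-10 claims carry no histology information")
        if not self.provenance:
            raise ValueError("evidence must carry provenance")


@dataclass(frozen=True)
class CohortAssignment:
    """Per-patient membership in the five cohorts plus contributing sources.

    Invariants: in_rare = in_rare_topography or in_rare_histology;
    in_consolidated requires in_rare and >= 2 distinct sources (and equals it
    under the default patient-level concordance rule); rare membership
    implies HNC-cohort membership; non-members carry no sources.
    """

    person_id: str
    in_hnc: bool
    in_rare_topography: bool
    in_rare_histology: bool
    in_rare: bool
    in_consolidated: bool
    sources: frozenset[Source] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.in_rare != (self.in_rare_topography or self.in_rare_histology):
            raise ValueError("in_rare must be the union of the two flavours")
        if self.in_rare and not self.in_hnc:
            raise ValueError("rare membership requires HNC-cohort membership")
        # under the default patient-level concordance rule consolidation is
        # exactly "rare with >= 2 sources"; the stricter same-flavour rule
        # can refuse consolidation despite two (cross-flavour) sources, so
        # the type only enforces the necessary direction
        if self.in_consolidated and not (self.in_rare and len(self.sources) >= 2):
            raise ValueError("consolidation requires rare status and >= 2 sources")
        if not self.in_rare and self.sources:
            raise ValueError("non-members must carry no sources")

    def sources_token(self) -> str:
        """Stable, order-normalized rendering of the source set."""
        return "+".join(sorted(s.value for s in self.sources))
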