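"""ADICAP pathology-code extraction and decoding.

ADICAP codes are 8-character strings embedded in French pathology reports;
four 2-character fields describe the sample type, the anatomical site, the
benign/malignant behaviour and the tumour histology.  This module locates
codes inside report text (next to an "ADICAP" cue or on a standalone code
line), decodes the four fields against a configurable dictionary, and turns
decoded codes into patient-level rare-topography / rare-histology evidence.

Rare-histology evidence requires a malignant, HNC-sited, non-squamous code;
rare-topography evidence requires a rare-topography site and (by default) a
malignant behaviour.  Unknown field values decode to an explicit UNKNOWN
record and never count as HNC, malignant or squamous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import ClinicalNote, Flavour, NoteType, Source, SourceEvidence

UNKNOWN = "UNKNOWN"

_FIELDS = ("sample_type", "site", "behaviour", "histology")


@dataclass(frozen=True)
class AdicapCode:
    """One extracted 8-character code with its source-text span."""

    raw: str
    sample_type: str
    site: str
    behaviour: str
    histology: str
    span: tuple[int, int]

    @classmethod
    def from_raw(
        cls,
        raw: str,
        span: tuple[int, int] = (0, 8),
        field_order: Sequence[str] = _FIELDS,
    ) -> "AdicapCode":
        if len(raw) != 8 or not raw.isalnum():
            raise ValueError(f"ADICAP code must be 8 alphanumeric characters, got {raw!r}")
        if sorted(field_order) != sorted(_FIELDS):
            raise ValueError(f"field_order must be a permutation of {_FIELDS}")
        parts = {name: raw[2 * i : 2 * i + 2] for i, name in enumerate(field_order)}
        return cls(raw=raw, span=span, **parts)


@dataclass(frozen=True)
class SiteEntry:
    label: str
    is_hnc: bool
    is_rare_topography: bool


@dataclass(frozen=True)
class BehaviourEntry:
    label: str
    is_malignant: bool


@dataclass(frozen=True)
class HistologyEntry:
    label: str
    is_scc: bool


_UNKNOWN_SITE = SiteEntry(UNKNOWN, False, False)
_UNKNOWN_BEHAVIOUR = BehaviourEntry(UNKNOWN, False)
_UNKNOWN_HISTOLOGY = HistologyEntry(UNKNOWN, False)

_TOKEN = r"(?<![0-9A-Za-z])([0-9A-Za-z]{8})(?![0-9A-Za-z])"


@dataclass(frozen=True)
class AdicapDictionary:
    """Decoding maps for the site, behaviour and histology fields.

    Lookups are total: codes absent from a map resolve to an explicit
    UNKNOWN entry with all flags false.
    """

    site_map: dict[str, SiteEntry]
    behaviour_map: dict[str, BehaviourEntry]
    histology_map: dict[str, HistologyEntry]
    field_order: tuple[str, ...] = _FIELDS
    cue_pattern: str = r"(?i)\bADICAP\b[\s:.\-]*"
    allow_standalone_line: bool = True
    require_malignant_for_topo: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "AdicapDictionary":
        return cls(
            site_map={
                k: SiteEntry(v["label"], bool(v["is_hnc"]), bool(v["is_rare_topography"]))
                for k, v in raw["sites"].items()
            },
            behaviour_map={
                k: BehaviourEntry(v["label"], bool(v["is_malignant"]))
                for k, v in raw["behaviours"].items()
            },
            histology_map={
                k: HistologyEntry(v["label"], bool(v["is_scc"]))
                for k, v in raw["histologies"].items()
            },
            field_order=tuple(raw.get("field_order", _FIELDS)),
            cue_pattern=raw.get("cue_pattern", cls.cue_pattern),
            allow_standalone_line=bool(raw.get("allow_standalone_line", True)),
            require_malignant_for_topo=bool(raw.get("require_malignant_for_topo", True)),
        )

    def site(self, code: str) -> SiteEntry:
        return self.site_map.get(code, _UNKNOWN_SITE)

    def behaviour(self, code: str) -> BehaviourEntry:
        return self.behaviour_map.get(code, _UNKNOWN_BEHAVIOUR)

    def histology(self, code: str) -> HistologyEntry:
        return self.histology_map.get(code, _UNKNOWN_HISTOLOGY)


@dataclass(frozen=True)
class DecodedAdicap:
    """Classification flags derived from one code by dictionary lookup."""

    code: AdicapCode
    site_label: str
    behaviour_label: str
    histology_label: str
    is_hnc: bool
    is_rare_topography: bool
    is_malignant: bool
    is_scc: bool


def extract_adicap(text: str, dictionary: Optional[AdicapDictionary] = None) -> list[AdicapCode]:
    """Find every ADICAP code in a report, in document order.

    A code is an 8-character alphanumeric token that is maximal (not part of
    a longer token) and appears in a code context: immediately after the cue
    pattern (default: the word "ADICAP" plus separators) or, if enabled,
    alone on its own line.  Spans are 0-based half-open offsets into
    ``text``; matches never overlap.
    """
    if dictionary is None:
        from .config import load_adicap_dictionary

        dictionary = load_adicap_dictionary()

    patterns = [re.compile(dictionary.cue_pattern + _TOKEN)]
    if dictionary.allow_standalone_line:
        patterns.append(re.compile(r"(?m)^[ \t]*" + _TOKEN + r"[ \t]*$"))

    found: dict[int, AdicapCode] = {}
    for pat in patterns:
        for m in pat.finditer(text):
            start, end = m.span(1)
            if any(s < end and start < e for s, e in (c.span for c in found.values())):
                continue
            found[start] = AdicapCode.from_raw(
                m.group(1).upper(), (start, end), dictionary.field_order
            )
    return [found[k] for k in sorted(found)]


def decode(code: AdicapCode, dictionary: AdicapDictionary) -> DecodedAdicap:
    """Decode one code field-by-field against the dictionary.

    All flags are pure conjunctions of dictionary lookups; an UNKNOWN site
    yields ``is_hnc=False`` and an UNKNOWN behaviour ``is_malignant=False``.
    """
    site = dictionary.site(code.site)
    behaviour = dictionary.behaviour(code.behaviour)
    histology = dictionary.histology(code.histology)
    return DecodedAdicap(
        code=code,
        site_label=site.label,
        behaviour_label=behaviour.label,
        histology_label=histology.label,
        is_hnc=site.is_hnc,
        is_rare_topography=site.is_rare_topography,
        is_malignant=behaviour.is_malignant,
        is_scc=histology.is_scc,
    )


@dataclass
class AdicapResult:
    """Patient-level outcome of ADICAP extraction."""

    adicap_hnc: bool
    evidence: list[SourceEvidence] = field(default_factory=list)


def adicap_evidence(
    notes: Iterable[ClinicalNote],
    dictionary: AdicapDictionary,
) -> AdicapResult:
    """Aggregate decoded codes of one patient's pathology reports.

    Emits at most one rare-topography and one rare-histology evidence item:

    * rare_histology — some code is malignant, HNC-sited and not squamous;
    * rare_topography — some code has a rare-topography site and, when the
      dictionary requires it (default), a malignant behaviour;
    * ``adicap_hnc`` — some code is malignant with an HNC site.

    Provenance records the note id and code span of the first qualifying
    code.  Multidisciplinary-meeting notes are rejected: only pathology
    reports are a classification source.
    """
    notes = list(notes)
    if any(n.note_type is not NoteType.PATHOLOGY_REPORT for n in notes):
        raise ValueError("ADICAP evidence is mined from pathology reports only")
    owners = {n.person_id for n in notes}
    if len(owners) > 1:
        raise ValueError(f"notes must belong to one patient, got {sorted(owners)}")

    adicap_hnc = False
    topo_prov: Optional[str] = None
    histo_prov: Optional[str] = None
    person_id = notes[0].person_id if notes else ""

    for note in sorted(notes, key=lambda n: n.note_id):
        for code in extract_adicap(note.text, dictionary):
            d = decode(code, dictionary)
            prov = f"{note.note_id}:{code.span[0]}-{code.span[1]}"
            if d.is_malignant and d.is_hnc:
                adicap_hnc = True
                if not d.is_scc and histo_prov is None:
                    histo_prov = prov
            topo_ok = d.is_rare_topography and (
                d.is_malignant or not dictionary.require_malignant_for_topo
            )
            if topo_ok and topo_prov is None:
                topo_prov = prov

    evidence = []
    if topo_prov is not None:
        evidence.append(
            SourceEvidence(person_id, Source.ADICAP, Flavour.RARE_TOPOGRAPHY, topo_prov)
        )
    if histo_prov is not None:
        evidence.append(
            SourceEvidence(person_id, Source.ADICAP, Flavour.RARE_HISTOLOGY, histo_prov)
        )
    return AdicapResult(adicap_hnc=adicap_hnc, evidence=evidence)
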