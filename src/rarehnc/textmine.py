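"""Lexicon/regex mining of pathology-report free text.

Finds histology and topography mentions with case- and accent-insensitive
regular expressions, then qualifies each mention for negation, hypothesis
and medical history with a ConText-style scoping rule: a qualifier trigger
acts on a mention when it occurs in the same sentence, on its configured
side of the mention, within a bounded token distance.  Only mentions that
are asserted (no qualifier set) become patient-level evidence.

Accent folding is performed character-by-character so the folded text has
the same length as the original: spans computed on the folded copy are valid
in the source text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .types import ClinicalNote, Flavour, NoteType, Source, SourceEvidence


def fold(text: str) -> str:
    """Lowercase and strip diacritics, preserving string length.

    Characters whose compatibility decomposition is not a single base
    character (ligatures such as "œ") are kept as-is so offsets survive.
    """
    out = []
    for ch in text:
        decomp = [c for c in unicodedata.normalize("NFKD", ch) if not unicodedata.combining(c)]
        out.append(decomp[0].lower() if len(decomp) == 1 else ch.lower())
    return "".join(out)


_SENTENCE_BREAK = re.compile(r"\.\s|[\n!?]")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans at '. ', newline, '!' and '?'.

    Returns 0-based half-open spans; whitespace-only segments are dropped,
    so no sentence is empty.  Text without terminators is one sentence.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_BREAK.finditer(text):
        end = m.end()
        if text[start:end].strip():
            spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


@dataclass(frozen=True)
class Qualifiers:
    negated: bool = False
    hypothesis: bool = False
    history: bool = False

    @property
    def any(self) -> bool:
        return self.negated or self.hypothesis or self.history


@dataclass(frozen=True)
class EntityMention:
    """One lexicon match in a note, with its qualification state."""

    note_id: str
    span: tuple[int, int]
    surface: str
    category: str  # "topography" | "histology"
    label: str
    is_rare: bool
    qualifiers: Qualifiers = Qualifiers()

    @property
    def asserted(self) -> bool:
        return not self.qualifiers.any


@dataclass(frozen=True)
class LexiconEntry:
    pattern: re.Pattern
    category: str
    label: str
    is_rare: bool


@dataclass(frozen=True)
class Lexicon:
    """Compiled concept patterns; labels are unique per category."""

    entries: tuple[LexiconEntry, ...]

    @classmethod
    def from_dict(cls, raw: dict) -> "Lexicon":
        entries = []
        seen: set[tuple[str, str]] = set()
        for e in raw["entries"]:
            if e["category"] not in ("topography", "histology"):
                raise ValueError(f"unknown lexicon category {e['category']!r}")
            key = (e["category"], e["label"])
            if key in seen:
                raise ValueError(f"duplicate lexicon label {key}")
            seen.add(key)
            entries.append(
                LexiconEntry(
                    pattern=re.compile(e["pattern"], re.IGNORECASE),
                    category=e["category"],
                    label=e["label"],
                    is_rare=bool(e["is_rare"]),
                )
            )
        return cls(entries=tuple(entries))

    def rare_labels(self, category: str) -> list[str]:
        return [e.label for e in self.entries if e.category == category and e.is_rare]


@dataclass(frozen=True)
class Trigger:
    pattern: re.Pattern
    direction: str  # "forward" | "backward"
    scope: int  # max whitespace tokens between trigger and mention


@dataclass(frozen=True)
class TriggerConfig:
    negation: tuple[Trigger, ...]
    hypothesis: tuple[Trigger, ...]
    history: tuple[Trigger, ...]

    @classmethod
    def from_dict(cls, raw: dict) -> "TriggerConfig":
        default_scope = int(raw.get("default_scope", 8))

        def build(items) -> tuple[Trigger, ...]:
            out = []
            for item in items:
                direction = item["direction"]
                if direction not in ("forward", "backward"):
                    raise ValueError(f"unknown trigger direction {direction!r}")
                out.append(
                    Trigger(
                        pattern=re.compile(item["pattern"], re.IGNORECASE),
                        direction=direction,
                        scope=int(item.get("scope", default_scope)),
                    )
                )
            return tuple(out)

        return cls(
            negation=build(raw.get("negation", [])),
            hypothesis=build(raw.get("hypothesis", [])),
            history=build(raw.get("history", [])),
        )


def match_lexicon(text: str, lexicon: Lexicon, note_id: str = "") -> list[EntityMention]:
    """All non-overlapping lexicon matches, unqualified, in document order.

    Conflicts are resolved earlier-start-first, then longest-match at equal
    start; matching is case- and accent-insensitive.
    """
    folded = fold(text)
    candidates: list[tuple[int, int, LexiconEntry]] = []
    for entry in lexicon.entries:
        for m in entry.pattern.finditer(folded):
            if m.start() != m.end():
                candidates.append((m.start(), m.end(), entry))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))

    mentions: list[EntityMention] = []
    occupied_end = 0
    for start, end, entry in candidates:
        if start < occupied_end:
            continue
        mentions.append(
            EntityMention(
                note_id=note_id,
                span=(start, end),
                surface=text[start:end],
                category=entry.category,
                label=entry.label,
                is_rare=entry.is_rare,
            )
        )
        occupied_end = end
    return mentions


def _tokens_between(folded: str, a: int, b: int) -> int:
    return len(folded[a:b].split())


def qualify(
    mention: EntityMention,
    sentences: list[tuple[int, int]],
    triggers: TriggerConfig,
    folded_text: str,
) -> EntityMention:
    """Return the mention with its negation/hypothesis/history flags set.

    A qualifier applies when one of its triggers matches in the sentence
    containing the mention, on the trigger's side (forward = before the
    mention, backward = after it), with at most ``scope`` tokens in between.
    Qualifiers are independent; span and label are never altered.
    """
    sent = next(
        ((s, e) for s, e in sentences if s <= mention.span[0] < e),
        (0, len(folded_text)),
    )
    s_start, s_end = sent
    sentence = folded_text[s_start:s_end]

    def fired(trigger_set: tuple[Trigger, ...]) -> bool:
        for trig in trigger_set:
            for m in trig.pattern.finditer(sentence):
                t_start, t_end = m.start() + s_start, m.end() + s_start
                if trig.direction == "forward" and t_end <= mention.span[0]:
                    if _tokens_between(folded_text, t_end, mention.span[0]) <= trig.scope:
                        return True
                elif trig.direction == "backward" and t_start >= mention.span[1]:
                    if _tokens_between(folded_text, mention.span[1], t_start) <= trig.scope:
                        return True
        return False

    return replace(
        mention,
        qualifiers=Qualifiers(
            negated=fired(triggers.negation),
            hypothesis=fired(triggers.hypothesis),
            history=fired(triggers.history),
        ),
    )


def extract_mentions(
    note: ClinicalNote, lexicon: Lexicon, triggers: TriggerConfig
) -> list[EntityMention]:
    """Match and qualify every lexicon concept in one note."""
    folded = fold(note.text)
    sentences = segment_sentences(note.text)
    return [
        qualify(m, sentences, triggers, folded)
        for m in match_lexicon(note.text, lexicon, note.note_id)
    ]


@dataclass
class NlpResult:
    """Patient-level outcome of free-text mining."""

    evidence: list[SourceEvidence] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)


def nlp_evidence(
    notes: Iterable[ClinicalNote],
    lexicon: Lexicon,
    triggers: TriggerConfig,
    histology_requires_hnc_context: bool = False,
) -> NlpResult:
    """Aggregate asserted rare mentions of one patient's pathology reports.

    Emits at most one rare-topography and one rare-histology evidence item
    (existential semantics over notes).  With
    ``histology_requires_hnc_context`` a rare-histology mention only counts
    when a topography mention occurs in the same sentence; the default is
    off because the report stream is already HNC-filtered upstream.
    """
    notes = list(notes)
    if any(n.note_type is not NoteType.PATHOLOGY_REPORT for n in notes):
        raise ValueError("NLP evidence is mined from pathology reports only")
    owners = {n.person_id for n in notes}
    if len(owners) > 1:
        raise ValueError(f"notes must belong to one patient, got {sorted(owners)}")
    person_id = notes[0].person_id if notes else ""

    all_mentions: list[EntityMention] = []
    topo_prov: Optional[str] = None
    histo_prov: Optional[str] = None

    for note in sorted(notes, key=lambda n: n.note_id):
        mentions = extract_mentions(note, lexicon, triggers)
        all_mentions.extend(mentions)
        sentences = segment_sentences(note.text)
        for m in mentions:
            if not (m.asserted and m.is_rare):
                continue
            prov = f"{m.note_id}:{m.span[0]}-{m.span[1]}"
            if m.category == "topography" and topo_prov is None:
                topo_prov = prov
            elif m.category == "histology" and histo_prov is None:
                if histology_requires_hnc_context:
                    sent = next(
                        ((s, e) for s, e in sentences if s <= m.span[0] < e), None
                    )
                    has_topo = sent is not None and any(
                        o.category == "topography"
                        and sent[0] <= o.span[0] < sent[1]
                        and o.asserted
                        for o in mentions
                    )
                    if not has_topo:
                        continue
                histo_prov = prov

    evidence = []
    if topo_prov is not None:
        evidence.append(
            SourceEvidence(person_id, Source.NLP, Flavour.RARE_TOPOGRAPHY, topo_prov)
        )
    if histo_prov is not None:
        evidence.append(
            SourceEvidence(person_id, Source.NLP, Flavour.RARE_HISTOLOGY, histo_prov)
        )
    return NlpResult(evidence=evidence, mentions=all_mentions)
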