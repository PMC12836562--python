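"""Mine a French pathology report for qualified histology/topography mentions.

Every lexicon match carries three independent qualifiers — negation,
hypothesis, medical history — detected by sentence-bounded, direction-aware
triggers.  Only asserted rare mentions (no qualifier set) become evidence.
"""

from rarehnc import ClinicalNote, NoteType, extract_mentions, load_lexicon, load_triggers, nlp_evidence

note = ClinicalNote(
    note_id="N1",
    person_id="P1",
    note_type=NoteType.PATHOLOGY_REPORT,
    text=(
        "Carcinome adénoïde kystique de la parotide.\n"
        "Pas de mélanome muqueux.\n"
        "Antécédent de lymphome en rémission."
    ),
)

lexicon, triggers = load_lexicon(), load_triggers()
for m in extract_mentions(note, lexicon, triggers):
    q = m.qualifiers
    print(
        f"{m.surface!r} [{m.category}/{m.label}] rare={m.is_rare} "
        f"negated={q.negated} hypothesis={q.hypothesis} history={q.history}"
    )

result = nlp_evidence([note], lexicon, triggers)
print("evidence flavours:", sorted(e.flavour.value for e in result.evidence))

# Only the first sentence is asserted: the adenoid cystic carcinoma (rare
# histology) of the parotid (rare topography) emits both evidence flavours;
# the negated melanoma and the historical lymphoma are suppressed.
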