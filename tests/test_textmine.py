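"""Free-text mining: sentence segmentation, lexicon matching, qualification."""

import unicodedata

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarehnc import (
    ClinicalNote,
    Flavour,
    NoteType,
    extract_mentions,
    match_lexicon,
    nlp_evidence,
    qualify,
    segment_sentences,
)
from rarehnc.textmine import fold


def _note(text, note_id="N1", person_id="P1", note_type=NoteType.PATHOLOGY_REPORT):
    return ClinicalNote(note_id, person_id, note_type, text)


# ---------------------------------------------------------------- sentences


@pytest.mark.parametrize(
    "text,n",
    [
        ("Pas de tumeur. Biopsie du sinus.", 2),
        ("", 0),
        ("texte sans terminateur", 1),
        ("Ligne un\nLigne deux\nLigne trois", 3),
        ("Un! Deux? Trois.", 3),
    ],
)
def test_segment_sentences_counts(text, n):
    spans = segment_sentences(text)
    assert len(spans) == n
    for s, e in spans:
        assert text[s:e].strip()  # no empty sentences
    # spans are ordered and non-overlapping
    assert all(spans[i][1] <= spans[i + 1][0] + 1 for i in range(len(spans) - 1))


# ------------------------------------------------------------------ lexicon


def test_match_lexicon_rare_histology_and_topography(lexicon):
    text = "carcinome adénoïde kystique de la parotide"
    mentions = match_lexicon(text, lexicon)
    by_cat = {m.category: m for m in mentions}
    assert by_cat["histology"].label == "carcinome_adenoide_kystique"
    assert by_cat["histology"].is_rare
    assert by_cat["topography"].label == "parotide"
    assert by_cat["topography"].is_rare
    for m in mentions:
        assert text[m.span[0] : m.span[1]] == m.surface


def test_match_lexicon_scc_and_common_site_not_rare(lexicon):
    mentions = match_lexicon("carcinome épidermoïde du larynx", lexicon)
    assert {m.label for m in mentions} == {"carcinome_epidermoide", "larynx"}
    assert not any(m.is_rare for m in mentions)


def test_match_lexicon_case_and_accent_insensitive(lexicon):
    """Folding oracle: lowercase+strip both pattern input and text by hand."""
    accented = "Carcinome Adénoïde Kystique"
    unaccented = "CARCINOME ADENOIDE KYSTIQUE"
    naive = "".join(
        c
        for c in unicodedata.normalize("NFKD", accented.lower())
        if not unicodedata.combining(c)
    )
    assert fold(accented) == naive == fold(unaccented).lower()
    m1 = match_lexicon(accented, lexicon)
    m2 = match_lexicon(unaccented, lexicon)
    assert [m.label for m in m1] == [m.label for m in m2] == ["carcinome_adenoide_kystique"]


def test_fold_preserves_length():
    for text in ("évoque un mélanome muqueux", "œsophage", "ÉTHMOÏDE à 100%"):
        assert len(fold(text)) == len(text)


def test_match_lexicon_non_overlapping_longest_wins(lexicon):
    # "carcinome mucoépidermoïde" must not be split into SCC + leftovers
    mentions = match_lexicon("carcinome mucoépidermoïde de la parotide", lexicon)
    histo = [m for m in mentions if m.category == "histology"]
    assert [m.label for m in histo] == ["carcinome_mucoepidermoide"]
    spans = sorted(m.span for m in mentions)
    assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))


# --------------------------------------------------------------- qualifiers


@pytest.mark.parametrize(
    "text,flag",
    [
        ("pas de carcinome adénoïde kystique", "negated"),
        ("absence de mélanome muqueux", "negated"),
        ("évoque un adénocarcinome", "hypothesis"),
        ("suspicion de sarcome", "hypothesis"),
        ("antécédent de carcinome épidermoïde", "history"),
        ("ATCD de lymphome", "history"),
    ],
)
def test_qualify_triggers(lexicon, triggers, text, flag):
    mentions = extract_mentions(_note(text), lexicon, triggers)
    assert mentions, text
    m = mentions[0]
    assert getattr(m.qualifiers, flag) is True
    others = {"negated", "hypothesis", "history"} - {flag}
    assert not any(getattr(m.qualifiers, o) for o in others)


def test_qualify_sentence_bounded(lexicon, triggers):
    text = "pas de récidive. Carcinome adénoïde kystique confirmé"
    mentions = extract_mentions(_note(text), lexicon, triggers)
    m = next(m for m in mentions if m.label == "carcinome_adenoide_kystique")
    assert m.qualifiers.negated is False and m.asserted


def test_qualify_scope_limit(lexicon, triggers):
    # ten filler tokens push the mention out of the 8-token trigger scope
    filler = "a b c d e f g h i j"
    text = f"pas de {filler} sarcome"
    mentions = extract_mentions(_note(text), lexicon, triggers)
    m = next(m for m in mentions if m.label == "sarcome")
    assert m.qualifiers.negated is False


def test_qualify_backward_trigger(lexicon, triggers):
    mentions = extract_mentions(_note("un sarcome est exclu"), lexicon, triggers)
    m = next(m for m in mentions if m.label == "sarcome")
    assert m.qualifiers.negated is True


def test_qualify_independent_qualifiers(lexicon, triggers):
    mentions = extract_mentions(
        _note("pas d'antécédent de lymphome"), lexicon, triggers
    )
    m = next(m for m in mentions if m.label == "lymphome")
    assert m.qualifiers.negated and m.qualifiers.history


@given(
    prefix=st.sampled_from(
        ["", "pas de ", "suspicion de ", "antécédent de ", "absence de "]
    ),
    term=st.sampled_from(["sarcome", "mélanome muqueux", "parotide", "larynx"]),
)
@settings(max_examples=30, deadline=None)
def test_qualify_never_changes_span_or_label(lexicon, triggers, prefix, term):
    text = f"{prefix}{term} observé"
    raw = match_lexicon(text, lexicon, "N1")
    note = _note(text)
    qualified = extract_mentions(note, lexicon, triggers)
    assert [(m.span, m.label, m.surface) for m in raw] == [
        (m.span, m.label, m.surface) for m in qualified
    ]


# ----------------------------------------------------------------- evidence


def test_nlp_evidence_both_flavours(lexicon, triggers):
    res = nlp_evidence(
        [_note("carcinome adénoïde kystique de la parotide")], lexicon, triggers
    )
    assert {e.flavour for e in res.evidence} == {
        Flavour.RARE_TOPOGRAPHY,
        Flavour.RARE_HISTOLOGY,
    }


def test_nlp_evidence_negation_gate(lexicon, triggers):
    res = nlp_evidence(
        [_note("pas d'argument pour un mélanome muqueux")], lexicon, triggers
    )
    assert res.evidence == []


def test_nlp_evidence_common_terms_no_evidence(lexicon, triggers):
    res = nlp_evidence(
        [_note("carcinome épidermoïde du larynx infiltrant")], lexicon, triggers
    )
    assert res.evidence == []


def test_nlp_evidence_deduplicated_per_flavour(lexicon, triggers):
    notes = [
        _note("sarcome de haut grade", note_id="N1"),
        _note("lymphome confirmé", note_id="N2"),
    ]
    res = nlp_evidence(notes, lexicon, triggers)
    assert [e.flavour for e in res.evidence] == [Flavour.RARE_HISTOLOGY]


def test_nlp_evidence_rejects_mdm(lexicon, triggers):
    with pytest.raises(ValueError, match="pathology"):
        nlp_evidence([_note("sarcome", note_type=NoteType.MDM_REPORT)], lexicon, triggers)


def test_nlp_evidence_invariant_to_note_order_and_duplication(lexicon, triggers):
    notes = [
        _note("adénocarcinome de la parotide", note_id="N1"),
        _note("biopsie normale", note_id="N2"),
    ]
    base = nlp_evidence(notes, lexicon, triggers)
    reordered = nlp_evidence(list(reversed(notes)), lexicon, triggers)
    duplicated = nlp_evidence(notes + [notes[0]], lexicon, triggers)
    key = lambda res: {(e.flavour, e.source) for e in res.evidence}
    assert key(base) == key(reordered) == key(duplicated)


def test_nlp_evidence_histology_context_switch(lexicon, triggers):
    note = _note("Mise en évidence d'un adénocarcinome.")
    loose = nlp_evidence([note], lexicon, triggers, histology_requires_hnc_context=False)
    strict = nlp_evidence([note], lexicon, triggers, histology_requires_hnc_context=True)
    assert [e.flavour for e in loose.evidence] == [Flavour.RARE_HISTOLOGY]
    assert strict.evidence == []
    co_located = _note("Adénocarcinome de la parotide.")
    strict2 = nlp_evidence([co_located], lexicon, triggers, histology_requires_hnc_context=True)
    assert Flavour.RARE_HISTOLOGY in {e.flavour for e in strict2.evidence}
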