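import pytest

from rarehnc import (
    ClaimRecord,
    ClinicalNote,
    Dataset,
    DiagnosisPosition,
    NoteType,
    Person,
    PipelineConfig,
    load_adicap_dictionary,
    load_codesets,
    load_lexicon,
    load_triggers,
)


@pytest.fixture(scope="session")
def codesets():
    return load_codesets()


@pytest.fixture(scope="session")
def adicap_dict():
    return load_adicap_dictionary()


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def triggers():
    return load_triggers()


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig.default()


def make_patient_dataset(
    person_id="P1",
    claims=(),
    note_texts=(),
    mdm_texts=(),
):
    """One-patient dataset: claims as (code, position) pairs, notes as text."""
    claim_records = [
        ClaimRecord(person_id, code, DiagnosisPosition(pos)) for code, pos in claims
    ]
    notes = [
        ClinicalNote(f"N{i}", person_id, NoteType.PATHOLOGY_REPORT, text)
        for i, text in enumerate(note_texts)
    ] + [
        ClinicalNote(f"M{i}", person_id, NoteType.MDM_REPORT, text)
        for i, text in enumerate(mdm_texts)
    ]
    return Dataset(persons=[Person(person_id)], claims=claim_records, notes=notes)


@pytest.fixture
def patient_dataset():
    return make_patient_dataset
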