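"""Delimited-table readers and writers.

The pipeline exchanges flat CSV files (UTF-8, header row) rather than a full
OMOP schema: the algorithm touches only persons, ICD-10 claims and clinical
notes.  Column names are remappable through a small schema-config mapping
(``{"claims": {"icd10_code": "condition_source_value"}, ...}``) so exports
from different warehouses can be ingested without rewriting files.  ICD-10
codes are normalized to dot-free uppercase on ingest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .types import (
    ClaimRecord,
    ClinicalNote,
    CohortAssignment,
    Dataset,
    DiagnosisPosition,
    GoldLabel,
    NoteType,
    Person,
    SchemaError,
    Sex,
    Source,
    SourceEvidence,
    normalize_icd10,
)

PathLike = Union[str, Path]

_DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "persons": ("person_id", "birth_year", "sex"),
    "claims": ("person_id", "icd10_code", "diagnosis_position", "claim_date"),
    "notes": ("note_id", "person_id", "note_type", "text", "note_date"),
}
_OPTIONAL: dict[str, tuple[str, ...]] = {
    "persons": ("birth_year", "sex"),
    "claims": ("claim_date",),
    "notes": ("note_date",),
}


def _read_table(
    path: PathLike, table: str, schema_config: Optional[Mapping[str, Mapping[str, str]]]
) -> pd.DataFrame:
    mapping = dict((schema_config or {}).get(table, {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {src: canonical for canonical, src in mapping.items()}
    df = df.rename(columns=rename)
    for col in _DEFAULT_COLUMNS[table]:
        if col not in df.columns:
            if col in _OPTIONAL[table]:
                df[col] = ""
            else:
                raise SchemaError(f"{table} table is missing mandatory column {col!r}")
    return df


def read_dataset(
    persons_path: PathLike,
    claims_path: PathLike,
    notes_path: PathLike,
    schema_config: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> Dataset:
    """Load and validate one EHR extract from three CSV files.

    Raises :class:`~rarehnc.types.SchemaError` naming any missing mandatory
    column and :class:`~rarehnc.types.IntegrityError` listing offending
    person ids when claims or notes reference unknown patients.
    """
    pdf = _read_table(persons_path, "persons", schema_config)
    cdf = _read_table(claims_path, "claims", schema_config)
    ndf = _read_table(notes_path, "notes", schema_config)

    persons = [
        Person(
            person_id=row.person_id,
            birth_year=int(row.birth_year) if row.birth_year else None,
            sex=Sex(row.sex) if row.sex else Sex.UNKNOWN,
        )
        for row in pdf.itertuples()
    ]
    claims = [
        ClaimRecord(
            person_id=row.person_id,
            icd10_code=normalize_icd10(row.icd10_code),
            diagnosis_position=DiagnosisPosition(row.diagnosis_position),
            claim_date=row.claim_date or None,
        )
        for row in cdf.itertuples()
    ]
    notes = [
        ClinicalNote(
            note_id=row.note_id,
            person_id=row.person_id,
            note_type=NoteType(row.note_type),
            text=row.text,
            note_date=row.note_date or None,
        )
        for row in ndf.itertuples()
    ]
    return Dataset(persons=persons, claims=claims, notes=notes)


def write_dataset(dataset: Dataset, out_dir: PathLike) -> dict[str, Path]:
    """Write persons.csv / claims.csv / notes.csv; inverse of read_dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "persons": out / "persons.csv",
        "claims": out / "claims.csv",
        "notes": out / "notes.csv",
    }
    pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "birth_year": "" if p.birth_year is None else p.birth_year,
                "sex": p.sex.value,
            }
            for p in dataset.persons
        ],
        columns=list(_DEFAULT_COLUMNS["persons"]),
    ).to_csv(paths["persons"], index=False)
    pd.DataFrame(
        [
            {
                "person_id": c.person_id,
                "icd10_code": c.icd10_code,
                "diagnosis_position": c.diagnosis_position.value,
                "claim_date": c.claim_date or "",
            }
            for c in dataset.claims
        ],
        columns=list(_DEFAULT_COLUMNS["claims"]),
    ).to_csv(paths["claims"], index=False)
    pd.DataFrame(
        [
            {
                "note_id": n.note_id,
                "person_id": n.person_id,
                "note_type": n.note_type.value,
                "text": n.text,
                "note_date": n.note_date or "",
            }
            for n in dataset.notes
        ],
        columns=list(_DEFAULT_COLUMNS["notes"]),
    ).to_csv(paths["notes"], index=False)
    return paths


_COHORT_COLUMNS = (
    "person_id",
    "in_hnc",
    "in_rare_topography",
    "in_rare_histology",
    "in_rare",
    "in_consolidated",
    "sources",
)


def write_cohort(assignments: Iterable[CohortAssignment], path: PathLike) -> Path:
    """Write cohort assignments to CSV: one row per patient, stable source token."""
    path = Path(path)
    pd.DataFrame(
        [
            {
                "person_id": a.person_id,
                "in_hnc": a.in_hnc,
                "in_rare_topography": a.in_rare_topography,
                "in_rare_histology": a.in_rare_histology,
                "in_rare": a.in_rare,
                "in_consolidated": a.in_consolidated,
                "sources": a.sources_token(),
            }
            for a in assignments
        ],
        columns=list(_COHORT_COLUMNS),
    ).to_csv(path, index=False)
    return path


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def read_cohort(path: PathLike) -> list[CohortAssignment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        CohortAssignment(
            person_id=row.person_id,
            in_hnc=_parse_bool(row.in_hnc),
            in_rare_topography=_parse_bool(row.in_rare_topography),
            in_rare_histology=_parse_bool(row.in_rare_histology),
            in_rare=_parse_bool(row.in_rare),
            in_consolidated=_parse_bool(row.in_consolidated),
            sources=frozenset(Source(t) for t in row.sources.split("+") if t),
        )
        for row in df.itertuples()
    ]


def write_evidence(evidence: Iterable[SourceEvidence], path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "person_id": e.person_id,
                "source": e.source.value,
                "flavour": e.flavour.value,
                "provenance": e.provenance,
            }
            for e in evidence
        ],
        columns=["person_id", "source", "flavour", "provenance"],
    ).to_csv(path, index=False)
    return path


def read_evidence(path: PathLike) -> list[SourceEvidence]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    from .types import Flavour

    return [
        SourceEvidence(row.person_id, Source(row.source), Flavour(row.flavour), row.provenance)
        for row in df.itertuples()
    ]


def write_gold(gold: Iterable[GoldLabel], path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "person_id": g.person_id,
                "is_rare_hnc": g.is_rare_hnc,
                "is_rare_topography": g.is_rare_topography,
                "is_rare_histology": g.is_rare_histology,
            }
            for g in gold
        ],
        columns=["person_id", "is_rare_hnc", "is_rare_topography", "is_rare_histology"],
    ).to_csv(path, index=False)
    return path


def read_gold(path: PathLike) -> list[GoldLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples():
        label = GoldLabel(
            person_id=row.person_id,
            is_rare_topography=_parse_bool(row.is_rare_topography),
            is_rare_histology=_parse_bool(row.is_rare_histology),
        )
        if hasattr(row, "is_rare_hnc") and _parse_bool(row.is_rare_hnc) != label.is_rare_hnc:
            raise ValueError(
                f"gold label for {row.person_id} violates is_rare_hnc = topo OR histo"
            )
        out.append(label)
    return out
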