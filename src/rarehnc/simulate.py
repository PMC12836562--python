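"""Seeded synthetic-EHR generator.

Emulates a hospital-warehouse extract around a head-and-neck-cancer (HNC)
cohort: demographics, ICD-10 claims with diagnosis positions, and
French-style pathology / multidisciplinary-meeting (MDM) notes with embedded
ADICAP code lines — together with gold labels drawn from the latent state
BEFORE any note is rendered, so no pipeline output can leak into the truth.

Error model.  Each data source observes the rarity status within its reach
— ICD-10 the rare-topography status (claims carry no histology), ADICAP and
free text the overall rare status — and is corrupted independently by a
per-source miss rate (sensitivity loss) and false rate (specificity loss).
A detected source reports every gold rarity flavour it can express; a false
positive fabricates one flavour.  In the zero-noise limit the pipeline
recovers gold exactly; at scale, measured per-source sensitivity and
specificity converge to 1 - miss_rate and 1 - false_rate.

Distractor sentences mention rare vocabulary under a negation, hypothesis or
history trigger; they exercise the qualifier gates and must never create
evidence.  All vocabulary comes from the same fixture lexicon and ADICAP
dictionary the engines consume, so lexicon-coverage failures cannot be
confused with logic failures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .types import (
    ClaimRecord,
    ClinicalNote,
    Dataset,
    DiagnosisPosition,
    Flavour,
    GoldLabel,
    NoteType,
    Person,
    Sex,
    Source,
)


@dataclass(frozen=True)
class SourceErrorRates:
    """Per-source corruption: miss = 1 - Se, false = 1 - Sp."""

    miss_rate: float
    false_rate: float

    def __post_init__(self) -> None:
        for name in ("miss_rate", "false_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# Defaults reproduce the marginal per-source error rates observed in the
# 100-patient expert validation study (misses among 22 rare patients, false
# positives among 78 non-rare): ICD-10 7/22 & 9/78, ADICAP 8/22 & 3/78,
# free-text NLP 1/22 & 9/78.
DEFAULT_ERROR_RATES: dict[Source, SourceErrorRates] = {
    Source.ICD10: SourceErrorRates(miss_rate=7 / 22, false_rate=9 / 78),
    Source.ADICAP: SourceErrorRates(miss_rate=8 / 22, false_rate=3 / 78),
    Source.NLP: SourceErrorRates(miss_rate=1 / 22, false_rate=9 / 78),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Prevalence defaults follow the source-population cohort marginals
    (45% rare topography and 19% rare histology among HNC patients; 85%
    pathology-report availability); the two rarity flavours are drawn
    independently.  ``p_hnc`` is high because the generator emulates an
    extract already enriched around the HNC funnel, not a whole-warehouse
    cancer population.
    """

    n_patients: int = 1000
    seed: int = 0
    p_hnc: float = 0.8
    p_rare_topo_given_hnc: float = 0.45
    p_rare_histo_given_hnc: float = 0.19
    p_report_available: float = 0.85
    error_rates: dict[Source, SourceErrorRates] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_RATES)
    )
    p_negation: float = 0.15
    p_hypothesis: float = 0.15
    p_history: float = 0.15
    p_mdm_note: float = 0.5
    # probability that a rare patient's miss is shared by ADICAP and NLP
    # (correlated pathology-report failure); 0 = independent sources.
    shared_miss: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "p_hnc",
            "p_rare_topo_given_hnc",
            "p_rare_histo_given_hnc",
            "p_report_available",
            "p_negation",
            "p_hypothesis",
            "p_history",
            "p_mdm_note",
            "shared_miss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.error_rates) != set(Source):
            raise ValueError("error_rates must cover ICD10, ADICAP and NLP")

    @staticmethod
    def noise_free(n_patients: int = 1000, seed: int = 0, **overrides) -> "GeneratorConfig":
        """All error and distractor rates zero, every report available."""
        defaults = dict(
            n_patients=n_patients,
            seed=seed,
            p_report_available=1.0,
            error_rates={s: SourceErrorRates(0.0, 0.0) for s in Source},
            p_negation=0.0,
            p_hypothesis=0.0,
            p_history=0.0,
        )
        defaults.update(overrides)
        return GeneratorConfig(**defaults)


@dataclass(frozen=True)
class PatientTruth:
    """Latent state of one patient, drawn before any record is rendered."""

    person_id: str
    is_hnc: bool
    rare_topography: bool
    rare_histology: bool
    report_available: bool
    detected: dict[Source, bool]
    flavours: dict[Source, frozenset[Flavour]]

    @property
    def is_rare(self) -> bool:
        return self.rare_topography or self.rare_histology


@dataclass
class GoldBundle:
    """Generated dataset plus the truth it was rendered from."""

    dataset: Dataset
    gold: list[GoldLabel]
    per_source_truth: dict[str, PatientTruth]
    config: GeneratorConfig


# --- vocabulary shared with the fixture lexicon / ADICAP dictionary -------

RARE_SITES = ("PA", "GS", "GA", "SI", "SE", "FN", "CV", "OM")
COMMON_HNC_SITES = ("OR", "LA", "HP", "OC", "LG", "AM")
NON_HNC_SITES = ("PU", "CN", "SN", "PR", "ES")
RARE_HISTOLOGY_CODES = ("40", "42", "43", "30", "59", "60", "67", "77")
SCC_HISTOLOGY_CODE = "92"
SAMPLE_TYPES = ("BH", "PI", "CY")

COMMON_HNC_CLAIMS = ("C320", "C101", "C099", "C020", "C139")
RARE_TOPO_CLAIMS = ("C07", "C080", "C110", "C300", "C301", "C310", "C410")
NON_HNC_CLAIMS = ("C509", "C61", "C189", "C340")
INCIDENTAL_CLAIMS = ("I10", "E119", "J449", "K219")

RARE_TOPO_SURFACES = (
    "la parotide",
    "la glande sous-maxillaire",
    "la glande salivaire accessoire",
    "le sinus maxillaire",
    "le sinus ethmoïdal",
    "la fosse nasale",
    "le cavum",
    "l'oreille moyenne",
)
RARE_HISTO_SURFACES = (
    "adénocarcinome",
    "carcinome adénoïde kystique",
    "carcinome mucoépidermoïde",
    "carcinome neuroendocrine",
    "mélanome muqueux",
    "esthésioneuroblastome",
    "sarcome",
    "lymphome",
)

_NEGATION_TEMPLATES = (
    "Pas de {t} identifié.",
    "Absence de {t} sur les prélèvements.",
    "Aucun argument pour un {t}.",
)
_HYPOTHESIS_TEMPLATES = (
    "Suspicion de {t} à confirmer.",
    "L'aspect évoque un {t}.",
)
_HISTORY_TEMPLATES = (
    "Antécédent de {t} traité.",
    "ATCD de {t} en rémission.",
)


def _draw_detection(
    rng: random.Random, target: bool, rates: SourceErrorRates
) -> bool:
    if target:
        return rng.random() >= rates.miss_rate
    return rng.random() < rates.false_rate


def draw_patient(rng: random.Random, person_id: str, config: GeneratorConfig) -> PatientTruth:
    """Draw one patient's latent state and per-source detection flags."""
    is_hnc = rng.random() < config.p_hnc
    topo = is_hnc and rng.random() < config.p_rare_topo_given_hnc
    histo = is_hnc and rng.random() < config.p_rare_histo_given_hnc
    rare = topo or histo
    report = rng.random() < config.p_report_available

    detected: dict[Source, bool] = {}
    flavours: dict[Source, frozenset[Flavour]] = {}

    shared_fail = rare and config.shared_miss > 0 and rng.random() < config.shared_miss

    for source in (Source.ICD10, Source.ADICAP, Source.NLP):
        target = topo if source is Source.ICD10 else rare
        hit = _draw_detection(rng, target, config.error_rates[source])
        if shared_fail and source in (Source.ADICAP, Source.NLP):
            hit = False
        detected[source] = hit
        if not hit:
            flavours[source] = frozenset()
        elif source is Source.ICD10:
            flavours[source] = frozenset({Flavour.RARE_TOPOGRAPHY})
        elif target:
            gold_flavours = set()
            if topo:
                gold_flavours.add(Flavour.RARE_TOPOGRAPHY)
            if histo:
                gold_flavours.add(Flavour.RARE_HISTOLOGY)
            flavours[source] = frozenset(gold_flavours)
        else:  # fabricated finding: one flavour
            flavours[source] = frozenset(
                {rng.choice((Flavour.RARE_TOPOGRAPHY, Flavour.RARE_HISTOLOGY))}
            )

    return PatientTruth(
        person_id=person_id,
        is_hnc=is_hnc,
        rare_topography=topo,
        rare_histology=histo,
        report_available=report,
        detected=detected,
        flavours=flavours,
    )


def _render_claims(rng: random.Random, truth: PatientTruth) -> list[ClaimRecord]:
    claims: list[ClaimRecord] = []
    pid = truth.person_id
    if truth.is_hnc:
        claims.append(
            ClaimRecord(
                pid,
                rng.choice(COMMON_HNC_CLAIMS),
                rng.choice((DiagnosisPosition.PRIMARY, DiagnosisPosition.RELATED)),
            )
        )
    else:
        claims.append(ClaimRecord(pid, rng.choice(NON_HNC_CLAIMS), DiagnosisPosition.PRIMARY))
    if truth.detected[Source.ICD10]:
        claims.append(
            ClaimRecord(
                pid,
                rng.choice(RARE_TOPO_CLAIMS),
                rng.choice(tuple(DiagnosisPosition)),
            )
        )
    if rng.random() < 0.5:
        claims.append(
            ClaimRecord(pid, rng.choice(INCIDENTAL_CLAIMS), DiagnosisPosition.ASSOCIATED)
        )
    return claims


def _adicap_code(rng: random.Random, truth: PatientTruth) -> str:
    fl = truth.flavours[Source.ADICAP]
    wants_topo = Flavour.RARE_TOPOGRAPHY in fl
    wants_histo = Flavour.RARE_HISTOLOGY in fl
    if wants_topo:
        site = rng.choice(RARE_SITES)
    elif wants_histo or truth.is_hnc:
        site = rng.choice(COMMON_HNC_SITES)
    else:
        site = rng.choice(NON_HNC_SITES)
    behaviour = "70" if (wants_topo or wants_histo or truth.is_hnc) else rng.choice(("70", "75"))
    histology = rng.choice(RARE_HISTOLOGY_CODES) if wants_histo else SCC_HISTOLOGY_CODE
    return rng.choice(SAMPLE_TYPES) + site + behaviour + histology


def render_pathology_note(
    truth: PatientTruth, rng: random.Random, config: GeneratorConfig, note_id: str
) -> ClinicalNote:
    """Render one pathology report consistent with the patient's truth.

    The report always carries exactly one ADICAP code line; free-text
    sentences assert rare vocabulary only when the NLP source is flagged as
    detecting, and distractor sentences (qualified rare mentions) are
    injected independently of the gold state.
    """
    sentences: list[str] = ["Compte rendu anatomopathologique."]
    sentences.append(f"Code ADICAP : {_adicap_code(rng, truth)}")

    fl = truth.flavours[Source.NLP]
    if Flavour.RARE_TOPOGRAPHY in fl:
        sentences.append(f"Prélèvement réalisé au niveau de {rng.choice(RARE_TOPO_SURFACES)}.")
    if Flavour.RARE_HISTOLOGY in fl:
        sentences.append(f"L'examen met en évidence un {rng.choice(RARE_HISTO_SURFACES)}.")
    if Flavour.RARE_HISTOLOGY not in fl:
        if truth.is_hnc:
            sentences.append("Aspect de carcinome épidermoïde bien différencié du larynx.")
        else:
            sentences.append("Prélèvement adressé pour examen histologique standard.")

    distractor_terms = RARE_HISTO_SURFACES + RARE_TOPO_SURFACES
    if rng.random() < config.p_negation:
        sentences.append(
            rng.choice(_NEGATION_TEMPLATES).format(t=rng.choice(distractor_terms))
        )
    if rng.random() < config.p_hypothesis:
        sentences.append(
            rng.choice(_HYPOTHESIS_TEMPLATES).format(t=rng.choice(distractor_terms))
        )
    if rng.random() < config.p_history:
        sentences.append(
            rng.choice(_HISTORY_TEMPLATES).format(t=rng.choice(distractor_terms))
        )

    return ClinicalNote(
        note_id=note_id,
        person_id=truth.person_id,
        note_type=NoteType.PATHOLOGY_REPORT,
        text="\n".join(sentences),
    )


def _render_mdm_note(rng: random.Random, person_id: str, note_id: str) -> ClinicalNote:
    # MDM reports are generated (they exist in real extracts) but are never a
    # classification source; some deliberately assert rare vocabulary.
    body = ["Réunion de concertation pluridisciplinaire ORL.", "Dossier discuté."]
    if rng.random() < 0.5:
        body.append(f"Présentation d'un cas de {rng.choice(RARE_HISTO_SURFACES)}.")
    return ClinicalNote(
        note_id=note_id,
        person_id=person_id,
        note_type=NoteType.MDM_REPORT,
        text=" ".join(body),
    )


def generate(config: GeneratorConfig) -> GoldBundle:
    """Generate a full synthetic extract plus gold labels and latent truth.

    Deterministic given the config (including the seed): two calls with an
    equal config produce identical bundles.
    """
    config.validate()
    rng = random.Random(config.seed)

    persons: list[Person] = []
    claims: list[ClaimRecord] = []
    notes: list[ClinicalNote] = []
    gold: list[GoldLabel] = []
    truths: dict[str, PatientTruth] = {}
    note_counter = 0

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        persons.append(
            Person(
                person_id=pid,
                birth_year=rng.randint(1935, 1985),
                sex=Sex.MALE if rng.random() < 2 / 3 else Sex.FEMALE,
            )
        )
        truth = draw_patient(rng, pid, config)
        truths[pid] = truth
        # gold is fixed here, before any rendering
        gold.append(
            GoldLabel(
                person_id=pid,
                is_rare_topography=truth.rare_topography,
                is_rare_histology=truth.rare_histology,
            )
        )
        claims.extend(_render_claims(rng, truth))
        if truth.report_available:
            note_counter += 1
            notes.append(render_pathology_note(truth, rng, config, f"N{note_counter:07d}"))
        if rng.random() < config.p_mdm_note:
            note_counter += 1
            notes.append(_render_mdm_note(rng, pid, f"N{note_counter:07d}"))

    dataset = Dataset(persons=persons, claims=claims, notes=notes)
    return GoldBundle(dataset=dataset, gold=gold, per_source_truth=truths, config=config)


def evaluation_universe(bundle: GoldBundle) -> set[str]:
    """The annotated universe an expert review would target: truly-HNC
    patients with an available pathology report (all of whom the pipeline's
    HNC cohort contains, since HNC patients always carry an HNC claim)."""
    return {
        pid
        for pid, t in bundle.per_source_truth.items()
        if t.is_hnc and t.report_available
    }
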