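"""Cohort assembly and multi-source consolidation.

Builds the five patient sets of the multimodal algorithm:

* **HNC cohort** — patients with an HNC ICD-10 claim (narrow position rule)
  or a malignant HNC-sited ADICAP code, AND at least one pathology report;
* **rare-topography subcohort** — HNC-cohort patients with rare-topography
  evidence from any source (ICD-10, ADICAP or free text);
* **rare-histology subcohort** — HNC-cohort patients with rare-histology
  evidence from ADICAP or free text;
* **rare cohort** — the union of the two subcohorts;
* **consolidated cohort** — rare patients flagged by at least two distinct
  data sources.

By default source concordance is counted at patient level across rarity
flavours (an ICD-10 topography hit plus an NLP histology hit consolidates);
``concordance_within_flavour`` restricts it to sources agreeing on the same
flavour.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

from .adicap import AdicapDictionary, adicap_evidence
from .icd10 import CodesetConfig, patient_icd10_evidence
from .textmine import Lexicon, TriggerConfig, nlp_evidence
from .types import CohortAssignment, Dataset, Flavour, Source, SourceEvidence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All rule sets consumed by the end-to-end pipeline."""

    codesets: CodesetConfig
    adicap: AdicapDictionary
    lexicon: Lexicon
    triggers: TriggerConfig
    histology_requires_hnc_context: bool = False
    concordance_within_flavour: bool = False

    @classmethod
    def default(cls, **overrides) -> "PipelineConfig":
        from .config import (
            load_adicap_dictionary,
            load_codesets,
            load_lexicon,
            load_triggers,
        )

        return cls(
            codesets=load_codesets(),
            adicap=load_adicap_dictionary(),
            lexicon=load_lexicon(),
            triggers=load_triggers(),
            **overrides,
        )


def build_hnc_cohort(dataset: Dataset, config: PipelineConfig) -> set[str]:
    """Patients with (HNC ICD-10 claim or HNC ADICAP code) and >= 1 pathology report."""
    cohort: set[str] = set()
    for person in dataset.persons:
        path_notes = dataset.pathology_notes_of(person.person_id)
        if not path_notes:
            continue
        icd = patient_icd10_evidence(dataset.claims_of(person.person_id), config.codesets)
        if icd.icd10_hnc:
            cohort.add(person.person_id)
            continue
        adi = adicap_evidence(path_notes, config.adicap)
        if adi.adicap_hnc:
            cohort.add(person.person_id)
    return cohort


def collect_evidence(dataset: Dataset, config: PipelineConfig) -> list[SourceEvidence]:
    """Run all three extraction engines over every patient."""
    evidence: list[SourceEvidence] = []
    for person in dataset.persons:
        evidence.extend(
            patient_icd10_evidence(dataset.claims_of(person.person_id), config.codesets).evidence
        )
        path_notes = dataset.pathology_notes_of(person.person_id)
        if path_notes:
            evidence.extend(adicap_evidence(path_notes, config.adicap).evidence)
            evidence.extend(
                nlp_evidence(
                    path_notes,
                    config.lexicon,
                    config.triggers,
                    config.histology_requires_hnc_context,
                ).evidence
            )
    return evidence


def build_assignments(
    dataset: Dataset,
    evidence: Iterable[SourceEvidence],
    config: PipelineConfig,
    hnc_cohort: Optional[set[str]] = None,
) -> list[CohortAssignment]:
    """Fuse per-source evidence into per-patient cohort assignments.

    Subcohort membership is evaluated only among the HNC cohort; evidence
    attached to patients outside it is dropped with a logged warning.
    Consolidation requires rare status plus >= 2 distinct sources (within
    one flavour if ``concordance_within_flavour`` is set).
    """
    if hnc_cohort is None:
        hnc_cohort = build_hnc_cohort(dataset, config)

    by_patient: dict[str, list[SourceEvidence]] = defaultdict(list)
    dropped: list[SourceEvidence] = []
    for ev in evidence:
        if ev.person_id not in hnc_cohort:
            dropped.append(ev)
            continue
        by_patient[ev.person_id].append(ev)
    if dropped:
        sample = sorted({e.person_id for e in dropped})[:5]
        logger.warning(
            "dropped %d evidence item(s) for %d patient(s) outside the HNC cohort "
            "(e.g. %s)",
            len(dropped),
            len({e.person_id for e in dropped}),
            ", ".join(sample),
        )

    assignments: list[CohortAssignment] = []
    for person in dataset.persons:
        pid = person.person_id
        evs = by_patient.get(pid, [])
        in_hnc = pid in hnc_cohort
        topo_sources = {e.source for e in evs if e.flavour is Flavour.RARE_TOPOGRAPHY}
        histo_sources = {e.source for e in evs if e.flavour is Flavour.RARE_HISTOLOGY}
        in_topo = bool(topo_sources)
        in_histo = bool(histo_sources)
        in_rare = in_topo or in_histo
        sources = frozenset(topo_sources | histo_sources) if in_rare else frozenset()
        if config.concordance_within_flavour:
            consolidated = in_rare and (len(topo_sources) >= 2 or len(histo_sources) >= 2)
        else:
            consolidated = in_rare and len(sources) >= 2
        assignments.append(
            CohortAssignment(
                person_id=pid,
                in_hnc=in_hnc,
                in_rare_topography=in_topo,
                in_rare_histology=in_histo,
                in_rare=in_rare,
                in_consolidated=consolidated,
                sources=sources,
            )
        )

    _assert_structure(assignments)
    return assignments


def _assert_structure(assignments: list[CohortAssignment]) -> None:
    """Runtime checks of the set-inclusion chain and inclusion-exclusion."""
    consolidated = sum(a.in_consolidated for a in assignments)
    rare = sum(a.in_rare for a in assignments)
    hnc = sum(a.in_hnc for a in assignments)
    topo = sum(a.in_rare_topography for a in assignments)
    histo = sum(a.in_rare_histology for a in assignments)
    both = sum(a.in_rare_topography and a.in_rare_histology for a in assignments)
    assert consolidated <= rare <= hnc, "cohort inclusion chain violated"
    assert rare == topo + histo - both, "inclusion-exclusion violated"


def run_pipeline(dataset: Dataset, config: Optional[PipelineConfig] = None):
    """Convenience wrapper: evidence + HNC cohort + assignments in one call.

    Returns ``(assignments, evidence, hnc_cohort)``.
    """
    if config is None:
        config = PipelineConfig.default()
    hnc_cohort = build_hnc_cohort(dataset, config)
    evidence = collect_evidence(dataset, config)
    assignments = build_assignments(dataset, evidence, config, hnc_cohort)
    kept = [e for e in evidence if e.person_id in hnc_cohort]
    return assignments, kept, hnc_cohort


def source_attribution(assignments: Iterable[CohortAssignment]) -> dict[str, dict[str, int]]:
    """Partition each cohort by the combination of contributing sources.

    Returns, per cohort, counts keyed by the order-normalized source token
    ("ADICAP+NLP", ...); counts over a cohort's partition sum to its size.
    """
    assignments = list(assignments)
    out: dict[str, dict[str, int]] = {}
    for cohort, flag in (
        ("rare_topography", "in_rare_topography"),
        ("rare_histology", "in_rare_histology"),
        ("rare", "in_rare"),
        ("consolidated", "in_consolidated"),
    ):
        counter: Counter[str] = Counter()
        for a in assignments:
            if getattr(a, flag):
                counter[a.sources_token()] += 1
        out[cohort] = dict(sorted(counter.items()))
    return out
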