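"""Cohort assembly: membership definitions, consolidation, attribution."""

import dataclasses
import itertools

import pytest

from rarehnc import (
    ClaimRecord,
    ClinicalNote,
    CohortAssignment,
    Dataset,
    DiagnosisPosition,
    Flavour,
    GeneratorConfig,
    NoteType,
    Person,
    Source,
    build_assignments,
    build_hnc_cohort,
    collect_evidence,
    generate,
    run_pipeline,
    source_attribution,
)

# One pathology-report sentence per single-flavour channel:
ADICAP_TOPO_LINE = "Code ADICAP : BHSI7092"  # malignant maxillary-sinus SCC -> rare topography
NLP_HISTO_LINE = "Mise en évidence d'un sarcome."  # asserted rare histology
NEUTRAL_LINE = "Examen sans particularité."


def _build_case(pid, icd10_rare, adicap_rare, nlp_rare, report):
    """One patient exercising a combination of evidence channels."""
    claims = [ClaimRecord(pid, "C320", DiagnosisPosition.PRIMARY)]  # common HNC claim
    if icd10_rare:
        claims.append(ClaimRecord(pid, "C301", DiagnosisPosition.ASSOCIATED))
    notes = []
    if report:
        lines = [NEUTRAL_LINE]
        if adicap_rare:
            lines.append(ADICAP_TOPO_LINE)
        if nlp_rare:
            lines.append(NLP_HISTO_LINE)
        notes.append(
            ClinicalNote(f"{pid}-note", pid, NoteType.PATHOLOGY_REPORT, "\n".join(lines))
        )
    return Person(pid), claims, notes


def _truth_table_dataset(report):
    persons, claims, notes = [], [], []
    cases = {}
    for i, (icd, adi, nlp) in enumerate(itertools.product([False, True], repeat=3)):
        pid = f"P{i}{'R' if report else 'X'}"
        p, c, n = _build_case(pid, icd, adi, nlp, report)
        persons.append(p)
        claims.extend(c)
        notes.extend(n)
        cases[pid] = (icd, adi, nlp)
    return Dataset(persons=persons, claims=claims, notes=notes), cases


def test_truth_table_with_reports(pipeline_config):
    """Eight patients covering every source combination, all with a report."""
    dataset, cases = _truth_table_dataset(report=True)
    assignments, evidence, hnc = run_pipeline(dataset, pipeline_config)
    by_id = {a.person_id: a for a in assignments}
    for pid, (icd, adi, nlp) in cases.items():
        a = by_id[pid]
        expected_sources = set()
        if icd:
            expected_sources.add(Source.ICD10)
        if adi:
            expected_sources.add(Source.ADICAP)
        if nlp:
            expected_sources.add(Source.NLP)
        assert a.in_hnc, pid  # common HNC claim + report
        assert a.in_rare_topography == (icd or adi), pid
        assert a.in_rare_histology == nlp, pid
        assert a.in_rare == bool(expected_sources), pid
        assert set(a.sources) == expected_sources, pid
        assert a.in_consolidated == (len(expected_sources) >= 2), pid


def test_truth_table_without_reports_excluded(pipeline_config):
    """Without a pathology report a patient never enters any cohort."""
    dataset, cases = _truth_table_dataset(report=False)
    assignments, evidence, hnc = run_pipeline(dataset, pipeline_config)
    assert hnc == set()
    for a in assignments:
        assert not a.in_hnc and not a.in_rare and a.sources == frozenset()


def test_hnc_membership_requires_pathology_report(pipeline_config):
    """An MDM note does not satisfy the pathology-report requirement."""
    pid = "P1"
    dataset = Dataset(
        persons=[Person(pid)],
        claims=[ClaimRecord(pid, "C11", DiagnosisPosition.PRIMARY)],
        notes=[ClinicalNote("M1", pid, NoteType.MDM_REPORT, "Dossier discuté.")],
    )
    assert build_hnc_cohort(dataset, pipeline_config) == set()


def test_hnc_membership_via_adicap_without_hnc_claim(pipeline_config):
    """A malignant HNC ADICAP code qualifies even without an HNC ICD-10 claim."""
    pid = "P1"
    dataset = Dataset(
        persons=[Person(pid)],
        claims=[ClaimRecord(pid, "E11", DiagnosisPosition.PRIMARY)],
        notes=[ClinicalNote("N1", pid, NoteType.PATHOLOGY_REPORT, "Code ADICAP : BHLA7092")],
    )
    assert build_hnc_cohort(dataset, pipeline_config) == {pid}


def test_cross_flavour_concordance_rule(pipeline_config):
    """ICD-10 topography + NLP histology consolidates by default, not under
    the strict same-flavour rule."""
    pid = "P0"
    person, claims, notes = _build_case(pid, icd10_rare=True, adicap_rare=False,
                                        nlp_rare=True, report=True)
    dataset = Dataset(persons=[person], claims=claims, notes=notes)
    default = run_pipeline(dataset, pipeline_config)[0][0]
    assert default.sources == frozenset({Source.ICD10, Source.NLP})
    assert default.in_consolidated is True

    strict_cfg = dataclasses.replace(pipeline_config, concordance_within_flavour=True)
    strict = run_pipeline(dataset, strict_cfg)[0][0]
    assert strict.in_rare and strict.in_consolidated is False


def test_same_flavour_concordance_consolidates_under_both_rules(pipeline_config):
    """ADICAP histology + NLP histology agree on the flavour: consolidated
    under the default and the strict rule alike."""
    pid = "P0"
    dataset = Dataset(
        persons=[Person(pid)],
        claims=[ClaimRecord(pid, "C320", DiagnosisPosition.PRIMARY)],
        notes=[
            ClinicalNote(
                "N1", pid, NoteType.PATHOLOGY_REPORT,
                "Code ADICAP : BHOR7040\n" + NLP_HISTO_LINE,
            )
        ],
    )
    for cfg in (pipeline_config,
                dataclasses.replace(pipeline_config, concordance_within_flavour=True)):
        a = run_pipeline(dataset, cfg)[0][0]
        assert a.in_consolidated, cfg.concordance_within_flavour


def test_evidence_outside_cohort_dropped_with_warning(pipeline_config, caplog):
    """Rare evidence for a non-cohort patient is discarded, never kept."""
    pid = "P1"
    # rare-topo claim in associated position only: evidence, but no HNC claim
    dataset = Dataset(
        persons=[Person(pid)],
        claims=[ClaimRecord(pid, "C301", DiagnosisPosition.ASSOCIATED)],
        notes=[],
    )
    evidence = collect_evidence(dataset, pipeline_config)
    assert len(evidence) == 1
    with caplog.at_level("WARNING", logger="rarehnc.cohort"):
        assignments = build_assignments(dataset, evidence, pipeline_config)
    assert "dropped" in caplog.text and not assignments[0].in_rare


def test_source_attribution_partition_and_conservation():
    mk = lambda pid, sources: CohortAssignment(
        pid, True, True, False, True, len(sources) >= 2, frozenset(sources)
    )
    assignments = [
        mk("P1", {Source.NLP}),
        mk("P2", {Source.NLP}),
        mk("P3", {Source.ADICAP, Source.NLP}),
    ]
    attr = source_attribution(assignments)
    assert attr["rare"] == {"NLP": 2, "ADICAP+NLP": 1}
    assert sum(attr["rare"].values()) == 3
    assert attr["consolidated"] == {"ADICAP+NLP": 1}
    assert source_attribution([])["rare"] == {}


# ------------------------------------------------- structural properties


@pytest.fixture(scope="module")
def noisy_run():
    bundle = generate(GeneratorConfig(n_patients=400, seed=11))
    assignments, evidence, hnc = run_pipeline(bundle.dataset)
    return bundle, assignments, evidence, hnc


def test_inclusion_chain_and_inclusion_exclusion(noisy_run):
    _, assignments, _, hnc = noisy_run
    cons = {a.person_id for a in assignments if a.in_consolidated}
    rare = {a.person_id for a in assignments if a.in_rare}
    topo = {a.person_id for a in assignments if a.in_rare_topography}
    histo = {a.person_id for a in assignments if a.in_rare_histology}
    assert cons <= rare <= hnc
    assert len(rare) == len(topo) + len(histo) - len(topo & histo)
    for a in assignments:
        assert a.in_consolidated == (a.in_rare and len(a.sources) >= 2)


def test_monotonicity_under_evidence_deletion(noisy_run, pipeline_config):
    """Removing one source's evidence can only shrink rare and consolidated."""
    bundle, assignments, evidence, hnc = noisy_run
    rare0 = sum(a.in_rare for a in assignments)
    cons0 = sum(a.in_consolidated for a in assignments)
    for source in Source:
        reduced = [e for e in evidence if e.source is not source]
        red_assignments = build_assignments(bundle.dataset, reduced, pipeline_config, hnc)
        assert sum(a.in_rare for a in red_assignments) <= rare0
        assert sum(a.in_consolidated for a in red_assignments) <= cons0


def test_single_source_evidence_never_consolidates(noisy_run, pipeline_config):
    bundle, _, evidence, hnc = noisy_run
    only_nlp = [e for e in evidence if e.source is Source.NLP]
    assignments = build_assignments(bundle.dataset, only_nlp, pipeline_config, hnc)
    assert not any(a.in_consolidated for a in assignments)
    assert all(a.sources <= {Source.NLP} for a in assignments)


def test_attribution_counts_sum_to_cohort_sizes(noisy_run):
    _, assignments, _, _ = noisy_run
    attr = source_attribution(assignments)
    for cohort, flag in (
        ("rare", "in_rare"),
        ("rare_topography", "in_rare_topography"),
        ("rare_histology", "in_rare_histology"),
        ("consolidated", "in_consolidated"),
    ):
        assert sum(attr[cohort].values()) == sum(getattr(a, flag) for a in assignments)


def test_assignment_invariants_enforced_at_construction():
    with pytest.raises(ValueError):
        CohortAssignment("P1", True, True, False, False, False, frozenset())
    with pytest.raises(ValueError):
        CohortAssignment("P1", False, True, False, True, False, frozenset({Source.NLP}))
    with pytest.raises(ValueError):
        CohortAssignment("P1", True, True, False, True, True, frozenset({Source.NLP}))
    with pytest.raises(ValueError):
        CohortAssignment("P1", True, False, False, False, False, frozenset({Source.NLP}))
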