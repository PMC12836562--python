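"""ICD-10 claim classification.

Classifies normalized ICD-10 codes into head-and-neck-cancer (HNC) relevance
and rare-topography status against configurable code sets, then lifts claim
classifications to patient level under two distinct diagnosis-position rules:
a narrow one (default primary/related) governing HNC-cohort membership and a
wide one (default primary/related/associated) governing rare-topography
evidence.  ICD-10 carries no histology information, so this source never
emits rare-histology evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .types import (
    ClaimRecord,
    DiagnosisPosition,
    Flavour,
    ICD10_PATTERN,
    Source,
    SourceEvidence,
)


class ClassificationError(ValueError):
    """A code could not be classified (malformed input, never silent)."""


@dataclass(frozen=True)
class CodesetConfig:
    """Code sets and position rules driving ICD-10 classification.

    ``hnc_codes`` and ``rare_topography_codes`` hold dot-free uppercase
    prefixes; with ``exact_match`` false a code matches an entry when it
    equals or extends it.  Codes in the rare list count as HNC-relevant even
    when absent from ``hnc_codes`` (e.g. C41).
    """

    hnc_codes: frozenset[str]
    rare_topography_codes: frozenset[str]
    hnc_positions: frozenset[DiagnosisPosition] = frozenset(
        {DiagnosisPosition.PRIMARY, DiagnosisPosition.RELATED}
    )
    rare_topo_positions: frozenset[DiagnosisPosition] = frozenset(
        {DiagnosisPosition.PRIMARY, DiagnosisPosition.RELATED, DiagnosisPosition.ASSOCIATED}
    )
    exact_match: bool = False

    def __post_init__(self) -> None:
        if not self.hnc_positions or not self.rare_topo_positions:
            raise ValueError("both position sets must be non-empty")

    @classmethod
    def from_dict(cls, raw: dict) -> "CodesetConfig":
        return cls(
            hnc_codes=frozenset(raw["hnc_codes"]),
            rare_topography_codes=frozenset(raw["rare_topography_codes"]),
            hnc_positions=frozenset(DiagnosisPosition(p) for p in raw["hnc_positions"]),
            rare_topo_positions=frozenset(
                DiagnosisPosition(p) for p in raw["rare_topo_positions"]
            ),
            exact_match=bool(raw.get("exact_match", False)),
        )

    def _matches(self, code: str, entries: frozenset[str]) -> bool:
        if self.exact_match:
            return code in entries
        return any(code == e or code.startswith(e) for e in entries)

    def classify(self, icd10_code: str) -> dict[str, bool]:
        """Classify one normalized code; see :func:`classify_code`."""
        if not ICD10_PATTERN.match(icd10_code):
            raise ClassificationError(
                f"cannot classify malformed ICD-10 code {icd10_code!r}"
            )
        rare = self._matches(icd10_code, self.rare_topography_codes)
        hnc = rare or self._matches(icd10_code, self.hnc_codes)
        return {"is_hnc": hnc, "is_rare_topography": rare}


def classify_code(icd10_code: str, config: CodesetConfig) -> dict[str, bool]:
    """Classify a normalized ICD-10 code.

    Returns ``{"is_hnc": ..., "is_rare_topography": ...}`` under prefix
    semantics (unless the config demands exact matching).  Malformed codes
    raise :class:`ClassificationError` rather than silently classifying as
    negative.
    """
    return config.classify(icd10_code)


@dataclass
class Icd10Result:
    """Patient-level outcome of ICD-10 classification."""

    icd10_hnc: bool
    evidence: list[SourceEvidence] = field(default_factory=list)


def patient_icd10_evidence(
    claims: Sequence[ClaimRecord] | Iterable[ClaimRecord], config: CodesetConfig
) -> Icd10Result:
    """Lift claim-level classification to one patient.

    ``icd10_hnc`` is true iff at least one claim is HNC-relevant in a
    position accepted by the narrow rule.  One rare-topography evidence item
    (at most) is emitted iff at least one claim matches the rare list in a
    position accepted by the wide rule; its provenance cites the smallest
    qualifying (code, position) pair, so the result does not depend on claim
    order.
    """
    claims = list(claims)
    owners = {c.person_id for c in claims}
    if len(owners) > 1:
        raise ValueError(f"claims must belong to one patient, got {sorted(owners)}")

    icd10_hnc = False
    rare_triggers: list[ClaimRecord] = []
    for claim in claims:
        flags = config.classify(claim.icd10_code)
        if flags["is_hnc"] and claim.diagnosis_position in config.hnc_positions:
            icd10_hnc = True
        if (
            flags["is_rare_topography"]
            and claim.diagnosis_position in config.rare_topo_positions
        ):
            rare_triggers.append(claim)
    trigger = (
        min(rare_triggers, key=lambda c: (c.icd10_code, c.diagnosis_position.value))
        if rare_triggers
        else None
    )

    evidence = []
    if trigger is not None:
        evidence.append(
            SourceEvidence(
                person_id=trigger.person_id,
                source=Source.ICD10,
                flavour=Flavour.RARE_TOPOGRAPHY,
                provenance=f"{trigger.icd10_code}@{trigger.diagnosis_position.value}",
            )
        )
    return Icd10Result(icd10_hnc=icd10_hnc, evidence=evidence)
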