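"""Diagnostic-accuracy evaluation against expert gold annotations.

Builds TP/FP/FN/TN confusion matrices over an annotated patient universe and
derives sensitivity, specificity, PPV and NPV on the percent scale.  Two
rounding modes exist: ``raw`` (full precision, the programmatic default) and
``paper`` (round half-to-even to integers, the convention of published
validation tables).  Zero-denominator metrics are UNDEFINED (``None``),
never 0 or 100: in a 100-patient validation set an empty predicted-positive
margin is meaningful.

The module also ships the reference validation-study confusion matrices of
the multimodal rare-HNC algorithm (100 expert-annotated head-and-neck-cancer
patients; counts per data source and per cohort) so the published metric
table can be recomputed on demand.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional

from .types import CohortAssignment, GoldLabel, Person, Sex, Source, SourceEvidence


class EvaluationError(ValueError):
    """Gold annotation missing for a universe member, or ill-formed inputs."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Se/Sp/PPV/NPV percentages; ``None`` marks a zero-denominator cell."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def _ratio(num: int, den: int, rounding: str) -> Optional[float]:
    if den == 0:
        return None
    exact = Fraction(100 * num, den)
    if rounding == "paper":
        # round() on Fraction is exact banker's rounding (half-to-even),
        # matching how published tables print e.g. 15/24 = 62.5% as 62.
        return float(round(exact))
    return float(exact)


def metrics(cm: ConfusionMatrix, rounding: str = "raw") -> MetricSet:
    """Compute Se, Sp, PPV and NPV (percent scale) from a confusion matrix.

    ``rounding="paper"`` rounds half-to-even to whole percent; ``"raw"``
    keeps full precision.  A zero denominator yields ``None``.
    """
    if rounding not in ("raw", "paper"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn, rounding),
        specificity=_ratio(cm.tn, cm.tn + cm.fp, rounding),
        ppv=_ratio(cm.tp, cm.tp + cm.fp, rounding),
        npv=_ratio(cm.tn, cm.tn + cm.fn, rounding),
    )


def confusion(
    predicted: set[str],
    gold: Mapping[str, bool],
    universe: set[str],
) -> ConfusionMatrix:
    """Tally a predicted patient set against boolean gold labels.

    ``gold`` must cover every universe member (missing labels raise
    :class:`EvaluationError` naming the patients); predictions outside the
    universe are rejected.
    """
    missing = sorted(universe - gold.keys())
    if missing:
        raise EvaluationError(f"gold annotation missing for patient(s): {missing}")
    stray = sorted(predicted - universe)
    if stray:
        raise EvaluationError(f"predictions outside the annotated universe: {stray}")
    tp = sum(1 for p in universe if p in predicted and gold[p])
    fp = sum(1 for p in universe if p in predicted and not gold[p])
    fn = sum(1 for p in universe if p not in predicted and gold[p])
    tn = sum(1 for p in universe if p not in predicted and not gold[p])
    return ConfusionMatrix(tp, fp, fn, tn)


# Confusion matrices of the 100-patient expert validation study of the
# multimodal rare-HNC identification algorithm: one row per single data
# source (scored against overall rare-HNC status) and one per cohort or
# subcohort.  (tp, fp, fn, tn).
REFERENCE_VALIDATION_MATRICES: dict[str, ConfusionMatrix] = {
    "icd10": ConfusionMatrix(15, 9, 7, 69),
    "adicap": ConfusionMatrix(14, 3, 8, 75),
    "nlp": ConfusionMatrix(21, 9, 1, 69),
    "rare_cohort": ConfusionMatrix(22, 25, 0, 53),
    "rare_topography": ConfusionMatrix(18, 24, 0, 58),
    "rare_histology": ConfusionMatrix(16, 5, 2, 77),
    "consolidated": ConfusionMatrix(20, 4, 2, 74),
}

REFERENCE_ROW_ORDER = tuple(REFERENCE_VALIDATION_MATRICES)


def reproduce_reference_tables(rounding: str = "paper") -> dict[str, dict]:
    """Recompute the published validation metrics from the stored counts."""
    return {
        name: {
            "tp": cm.tp,
            "fp": cm.fp,
            "fn": cm.fn,
            "tn": cm.tn,
            "total": cm.total,
            **metrics(cm, rounding).__dict__,
        }
        for name, cm in REFERENCE_VALIDATION_MATRICES.items()
    }


def _gold_maps(gold: Iterable[GoldLabel]) -> dict[str, GoldLabel]:
    by_id = {}
    for g in gold:
        if g.person_id in by_id:
            raise EvaluationError(f"duplicate gold label for patient {g.person_id}")
        by_id[g.person_id] = g
    return by_id


def evaluate_all(
    assignments: Iterable[CohortAssignment],
    evidence: Iterable[SourceEvidence],
    gold: Iterable[GoldLabel],
    universe: set[str],
    rounding: str = "raw",
) -> dict[str, dict]:
    """Score the pipeline on an annotated universe, one row per table line.

    Single-source rows score "patient has >= 1 rare evidence item from that
    source" against overall rare-HNC gold status (the convention of the
    published per-source table; note it structurally penalises ICD-10, which
    cannot see histology-only rare cases).  An additional
    ``icd10_topography`` row scores ICD-10 against rare-topography gold
    only, i.e. within the source's reach.  Cohort rows score the fused
    memberships against the matching gold flag.
    """
    assignments = list(assignments)
    gold_by_id = _gold_maps(gold)

    by_source: dict[Source, set[str]] = {s: set() for s in Source}
    for ev in evidence:
        if ev.person_id in universe:
            by_source[ev.source].add(ev.person_id)

    rare_gold = {p: g.is_rare_hnc for p, g in gold_by_id.items()}
    topo_gold = {p: g.is_rare_topography for p, g in gold_by_id.items()}
    histo_gold = {p: g.is_rare_histology for p, g in gold_by_id.items()}

    member = lambda flag: {
        a.person_id for a in assignments if getattr(a, flag) and a.person_id in universe
    }

    rows: dict[str, tuple[set[str], Mapping[str, bool]]] = {
        "icd10": (by_source[Source.ICD10], rare_gold),
        "adicap": (by_source[Source.ADICAP], rare_gold),
        "nlp": (by_source[Source.NLP], rare_gold),
        "rare_cohort": (member("in_rare"), rare_gold),
        "rare_topography": (member("in_rare_topography"), topo_gold),
        "rare_histology": (member("in_rare_histology"), histo_gold),
        "consolidated": (member("in_consolidated"), rare_gold),
        "icd10_topography": (by_source[Source.ICD10], topo_gold),
    }

    report: dict[str, dict] = {}
    for name, (predicted, gold_map) in rows.items():
        cm = confusion(predicted, gold_map, universe)
        report[name] = {
            "tp": cm.tp,
            "fp": cm.fp,
            "fn": cm.fn,
            "tn": cm.tn,
            "total": cm.total,
            **metrics(cm, rounding).__dict__,
        }
    return report


def format_metrics_table(report: dict[str, dict]) -> str:
    """Render an evaluation report as a fixed-width text table."""
    header = f"{'row':<18}{'TP':>6}{'FP':>6}{'FN':>6}{'TN':>6}{'Total':>7}{'Se%':>7}{'Sp%':>7}{'PPV%':>7}{'NPV%':>7}"
    lines = [header, "-" * len(header)]

    def cell(v: Optional[float]) -> str:
        if v is None:
            return "--"
        return f"{v:.0f}" if float(v).is_integer() else f"{v:.1f}"

    for name, r in report.items():
        lines.append(
            f"{name:<18}{r['tp']:>6}{r['fp']:>6}{r['fn']:>6}{r['tn']:>6}{r['total']:>7}"
            f"{cell(r['sensitivity']):>7}{cell(r['specificity']):>7}"
            f"{cell(r['ppv']):>7}{cell(r['npv']):>7}"
        )
    return "\n".join(lines)


def cohort_summary(
    assignments: Iterable[CohortAssignment], persons: Iterable[Person], reference_year: int = 2024
) -> dict[str, dict]:
    """Median age, IQR and sex ratio per cohort, with missingness counts."""
    persons_by_id = {p.person_id: p for p in persons}
    assignments = list(assignments)
    out: dict[str, dict] = {}
    for cohort, flag in (
        ("hnc", "in_hnc"),
        ("rare", "in_rare"),
        ("rare_topography", "in_rare_topography"),
        ("rare_histology", "in_rare_histology"),
        ("consolidated", "in_consolidated"),
    ):
        members = [persons_by_id[a.person_id] for a in assignments if getattr(a, flag)]
        ages = sorted(
            reference_year - p.birth_year for p in members if p.birth_year is not None
        )
        males = sum(1 for p in members if p.sex is Sex.MALE)
        females = sum(1 for p in members if p.sex is Sex.FEMALE)
        if ages:
            # "inclusive" = linear interpolation on the sorted sample, the
            # same convention as numpy.percentile's default.
            if len(ages) >= 2:
                q1, _, q3 = statistics.quantiles(ages, n=4, method="inclusive")
            else:
                q1 = q3 = float(ages[0])
            age_stats = {"median": statistics.median(ages), "q1": q1, "q3": q3}
        else:
            age_stats = {"median": None, "q1": None, "q3": None}
        out[cohort] = {
            "n": len(members),
            "age": age_stats,
            "missing_birth_year": sum(1 for p in members if p.birth_year is None),
            "sex_ratio_m_f": (males / females) if females else None,
            "unknown_sex": sum(1 for p in members if p.sex is Sex.UNKNOWN),
        }
    return out


def nlp_false_positive_rates(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Two distinct 'false-positive rate' readings, labelled explicitly.

    ``fp_over_total`` is FP divided by the whole annotated universe;
    ``fp_over_gold_negative`` is FP/(FP+TN) = 1 - specificity.  Both are on
    the percent scale.
    """
    return {
        "fp_over_total": 100 * cm.fp / cm.total if cm.total else None,
        "fp_over_gold_negative": 100 * cm.fp / (cm.fp + cm.tn) if (cm.fp + cm.tn) else None,
    }
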