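# Methods

## The phenotyping problem

Rare head-and-neck cancers (HNCs) — rare either by topography (salivary
glands, sinus, nasal fossa, nasopharynx, middle ear, per the REFCOR
definition) or by histology (any non-squamous type) — are too infrequent for
single-centre chart review, and no single EHR signal identifies them
reliably: ICD-10 claims carry no histology, pathology codes and reports
exist only where a specimen was taken, and free text is contaminated by
negated, hypothetical and historical mentions.  `rarehnc` implements a
rule-based multimodal classifier over three evidence channels and evaluates
it the way such algorithms are validated in practice: against a
chart-reviewed gold standard, with sensitivity (Se), specificity (Sp), PPV
and NPV per channel and per fused cohort.

## The algorithm

Patient-level evidence is produced independently by three engines, each
existentially quantified over a patient's records ("at least one"):

* **ICD-10** — a claim code matches a configurable set by prefix (dot-free,
  uppercase; `C110` matches `C11`).  Two distinct diagnosis-position rules
  apply: HNC-cohort membership requires a primary or related HNC code, while
  rare-topography evidence admits primary, related or associated positions
  (the claim lists differ in the two rules' sources, and both are config).
  The default rare-topography claim list is C07, C08, C11, C41, C300, C301,
  C31.  C41 (bone) is kept as listed even though it is not head-and-neck
  specific; no anatomical sub-filtering is attempted.  This channel can
  never emit rare-histology evidence.
* **ADICAP** — 8-character pathology codes are located in report text next
  to an "ADICAP" cue or on a standalone code line, sliced into four
  2-character fields (sample type, site, behaviour, histology — the
  positional order is a dictionary constant, since published layouts vary),
  and decoded against a dictionary.  Rare-histology evidence requires
  malignant AND HNC-sited AND non-squamous; rare-topography evidence
  requires a rare site and, by default, malignancy
  (`require_malignant_for_topo`, exposed because the topography rule could
  be read either way; the cohort is cancer patients, so the default gates).
  Unknown field values decode to an explicit UNKNOWN entry with all flags
  false — never a silent default.
* **Free text (NLP)** — case- and accent-insensitive regular-expression
  lexicon matching (longest match at equal start, earlier start on overlap)
  followed by ConText-style qualification: a mention is negated /
  hypothetical / historical when a trigger of that class occurs in the same
  sentence, on the trigger's configured side, within a bounded token
  distance (default 8).  Only asserted rare mentions become evidence.
  Accent folding is character-wise and length-preserving, so spans computed
  on the folded text index the original.

Fusion then builds five nested sets.  The **HNC cohort** is patients with at
least one pathology report AND an HNC ICD-10 claim (narrow position rule) or
a malignant HNC ADICAP code.  Within it, the **rare-topography** and
**rare-histology subcohorts** collect patients with at least one evidence
item of that flavour; the **rare cohort** is their union; the **consolidated
cohort** is rare patients flagged by ≥ 2 distinct sources.  Concordance is
counted at patient level across flavours by default (an ICD-10 topography
hit plus an NLP histology hit consolidates); a strict same-flavour variant
is available as `concordance_within_flavour`.  Evidence attached to patients
outside the HNC cohort is dropped with a logged warning.  Multidisciplinary-
meeting reports are represented in the data model and the generator but are
never a classification source.

## Metrics

Confusion matrices are tallied over an annotated universe only — no
prevalence extrapolation.  Se = 100·TP/(TP+FN), Sp = 100·TN/(TN+FP),
PPV = 100·TP/(TP+FP), NPV = 100·TN/(TN+FN), computed on exact rationals.
`raw` mode (default) returns full precision; `paper` mode rounds
half-to-even to whole percent, the convention under which every cell of the
published validation table reproduces, including the one exact half
(PPV 15/24 = 62.5 → 62).  Zero-denominator metrics serialize as null, never
as 0 or 100.  Per-source table rows score each channel alone against overall
rare status (which structurally penalises ICD-10, blind to histology-only
cases); an extra `icd10_topography` row scores ICD-10 within its reach.
Two readings of an NLP "false-positive rate" — FP/total and FP/(FP+TN) —
are exposed under distinct names because the two differ materially in small
validation sets.

## Synthetic-EHR generator

The generator emulates the statistical shape of a warehouse extract already
enriched around the HNC funnel, not a whole-hospital population.  Per
patient it draws, in a fixed order from one seeded PRNG: HNC status
(`p_hnc`, default 0.8), rare topography and rare histology independently
given HNC (defaults 0.45 and 0.19, the cohort-level marginals of the study
population; because the two flavours are drawn independently the synthetic
rare fraction ≈ 0.55 slightly exceeds the real ≈ 0.49, where flavours are
positively correlated), pathology-report availability (default 0.85), then
per-source detection flags.  Gold labels are fixed at this point, before any
record is rendered, so rendering bugs can change pipeline output but never
the truth (no-leakage).

Detection errors are applied at patient level against the status each source
can observe: ICD-10 miss/false rates act on the rare-topography status,
ADICAP and NLP rates on the overall rare status, and a detected source
reports every gold flavour within its reach (a false positive fabricates one
flavour at random).  Default rates are the validation-study marginals:
ICD-10 miss 7/22, false 9/78; ADICAP 8/22 and 3/78; NLP 1/22 and 9/78.
Consequences, by construction:

* with all rates zero the pipeline reproduces gold patient-for-patient, and
  every metric that is defined is 100 on the cohort rows and on per-source
  rows scored against the source-appropriate gold;
* at scale, measured single-source Se → 100·(1 − miss) and
  Sp → 100·(1 − false) (binomial sampling error only), e.g. NLP ≈ 95/88.

Sources err independently given the latent state; a `shared_miss` knob
introduces correlated ADICAP+NLP misses (e.g. an uninformative specimen) but
defaults to 0 because no joint source-agreement distribution is available to
calibrate it.  Rendered pathology reports carry exactly one ADICAP code line
plus template sentences drawn from the same fixture lexicon the NLP engine
consumes; distractor sentences (rates `p_negation` etc., default 0.15 each)
mention rare vocabulary under a qualifier trigger and must never create
evidence.  Outside distractors, the generator emits no lexicon vocabulary it
does not intend, so lexicon-coverage failures and logic failures are
separable in tests.

What the generator does **not** model: realistic clinical narrative, report
sections, spelling noise, multiple pathology reports per patient, hospital
clustering, calendar time, and correlation between the two rarity flavours.
Passing tests therefore demonstrate the correctness of the extraction and
fusion logic under the stated error model, not the real-world accuracy of
the shipped lexicon or dictionary, which are documented fixtures: the
site/histology inventories approximate the REFCOR definitions, and the
official ADICAP thesaurus is deliberately out of scope (all classification
logic is dictionary-driven, so a real thesaurus is a data swap).

## Numerical and design choices

* Percent values are computed as `fractions.Fraction`; `paper` rounding uses
  Python's exact banker's rounding on rationals, so no floating-point
  half-case ambiguity exists.
* Age quantiles use linear interpolation on the sorted sample ("inclusive"
  method, identical to `numpy.percentile` defaults); ages derive from birth
  year against a fixed reference year (default 2024), as the algorithm
  itself never uses dates (prevalence design, dates optional everywhere).
* Lexicon match conflicts: longest match wins at equal start, earlier start
  wins on overlap; matches never overlap across categories.
* Sentence segmentation splits at ". ", newline, "!" and "?"; a trailing
  period without following whitespace stays inside its sentence.
* Evidence is deduplicated per (patient, source, flavour); provenance keeps
  the first qualifying record under a deterministic ordering (sorted note
  ids; smallest code/position pair for claims), so results are invariant to
  input order.
* One patient may have several pathology reports; evidence is lifted to
  patient level by existential quantification, the assumed reading of
  "at least one".
* Problem sizes in the test suite and acceptance script: hand-built
  fixtures for definitions, n = 300–1000 for deterministic properties,
  n = 10 000 for calibration (3-point binomial tolerance at ~22% prevalence
  gives ample margin at that size).

## Known limitations

* The shipped code sets, dictionary, lexicon and triggers are documented
  defaults, not validated clinical artifacts; deployments must substitute
  local rule sets (all are YAML, hot-swappable).
* The qualifier scoper is a deliberate ConText-style simplification: no
  termination clues, no coordination handling, fixed token scopes.
* The cross-flavour consolidation default follows the printed definition of
  "concordance of data sources"; whether concordance should be restricted to
  the same rarity flavour is genuinely ambiguous, so both rules are
  implemented and the choice is a single config switch.
* Real-data cohort sizes and source-overlap Venn counts depend on an
  access-restricted warehouse and are not reproduction targets; synthetic
  attribution counts are illustrative only.
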