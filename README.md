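# rarehnc

Multimodal identification of **rare head-and-neck-cancer (HNC) patients**
from hospital EHR extracts, with a full evaluation harness and a synthetic
data generator.

Rare HNCs — rare by topography (salivary glands, sinus, nasal fossa,
nasopharynx, middle ear) or by histology (any non-squamous-cell type) — are
hard to find in clinical data warehouses: ICD-10 claims carry no histology,
pathology codes exist only where a specimen was taken, and free text is full
of negated, hypothetical and historical mentions.  `rarehnc` fuses three
evidence channels per patient:

1. **ICD-10 claims** — configurable prefix code sets with two
   diagnosis-position rules (narrow primary/related for cohort membership,
   wide primary/related/associated for rare-topography evidence; default
   rare claim list C07, C08, C11, C41, C300, C301, C31);
2. **ADICAP pathology codes** — 8-character codes located in report text,
   decoded field-wise (sample type / site / behaviour / histology) against a
   swappable dictionary, gated on malignancy;
3. **Free-text NLP** — case- and accent-insensitive regex lexicon matching
   with ConText-style negation / hypothesis / history qualification
   (sentence-bounded, direction-aware, token-scoped triggers).

Fusion yields five nested patient sets — HNC cohort (HNC code + ≥ 1
pathology report), rare-topography and rare-histology subcohorts, their
union (**rare cohort**), and the **consolidated cohort** (rare status
flagged by ≥ 2 distinct sources).  The evaluation module scores any of these
against expert gold labels as TP/FP/FN/TN with sensitivity, specificity, PPV
and NPV:

    Se = 100·TP/(TP+FN)   Sp = 100·TN/(TN+FP)
    PPV = 100·TP/(TP+FP)  NPV = 100·TN/(TN+FN)

computed on exact rationals, with `paper` mode rounding half-to-even to
whole percent (the convention of published validation tables) and undefined
cells reported as null.  A seeded synthetic-EHR generator (French-style
pathology notes with embedded ADICAP lines, partially concordant claims,
85% report availability, per-source miss/false rates) makes the whole
pipeline runnable and testable with no access to a real warehouse.

Intended users: clinical-informatics and epidemiology teams building or
auditing rule-based phenotyping algorithms on OMOP-style extracts.

## Worked example

```python
from rarehnc import (GeneratorConfig, generate, run_pipeline,
                     evaluation_universe, evaluate_all, format_metrics_table)

bundle = generate(GeneratorConfig(n_patients=2000, seed=7))
assignments, evidence, hnc = run_pipeline(bundle.dataset)
report = evaluate_all(assignments, evidence, bundle.gold,
                      evaluation_universe(bundle), rounding="paper")
print(format_metrics_table(report))
```

prints (seed 7):

```
row                   TP    FP    FN    TN  Total    Se%    Sp%   PPV%   NPV%
-----------------------------------------------------------------------------
icd10                434    81   344   553   1412     56     87     84     62
adicap               508    28   270   606   1412     65     96     95     69
nlp                  749    73    29   561   1412     96     88     91     95
rare_cohort          772   168     6   466   1412     99     74     82     99
rare_topography      632   141     4   635   1412     99     82     82     99
rare_histology       270    54     4  1084   1412     99     95     83    100
consolidated         650    13   128   621   1412     84     98     98     83
icd10_topography     413   102   223   674   1412     65     87     80     75
```

Of 2000 synthetic patients, 1452 enter the HNC cohort (HNC code plus an
available pathology report), 980 are flagged rare by at least one source and
671 by at least two.  The single-source rows show each channel scored alone
against overall rare status: free text is the most sensitive channel (Se 96)
but ICD-10, blind to histology-only cases, is structurally penalised (the
`icd10_topography` row scores it within its reach).  Requiring two
concordant sources (`consolidated`) trades sensitivity for much better
specificity and PPV — the core rationale of the multimodal design.

The `examples/` directory holds one short narrative script per capability
(ADICAP decoding, qualified text mining, full pipeline, validation-table
reproduction), and the `rarehnc` command exposes the same stages from a
shell (`simulate`, `build-cohort`, `evaluate`, `reproduce-tables`,
`run-all`).  All rule sets — code sets, ADICAP dictionary, lexicon,
qualifier triggers — are YAML files under `src/rarehnc/resources/`, shipped
as documented defaults and replaceable per deployment.

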