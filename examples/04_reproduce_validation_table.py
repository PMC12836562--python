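"""Recompute the published validation metrics from the stored counts.

The 100-patient expert validation of the multimodal algorithm is summarised
by seven confusion matrices (three single-source rows, four cohort rows).
Feeding the counts through the metric engine in `paper` rounding mode
(half-to-even on the percent scale) reproduces every printed percentage,
including PPV 15/24 = 62.5 -> 62.
"""

from rarehnc import format_metrics_table, reproduce_reference_tables

print(format_metrics_table(reproduce_reference_tables(rounding="paper")))
print()
print("raw (unrounded) consolidated row:")
raw = reproduce_reference_tables(rounding="raw")["consolidated"]
print({k: round(v, 2) for k, v in raw.items() if isinstance(v, float)})
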