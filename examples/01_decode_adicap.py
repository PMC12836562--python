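"""Extract and decode ADICAP codes from a pathology-report snippet.

ADICAP codes are 8-character strings (sample type, site, behaviour,
histology — 2 characters each) that French pathology reports carry.  The
site field decides head-and-neck relevance and rare-topography status; the
behaviour field gates everything on malignancy; the histology field decides
whether the tumour type is squamous (common) or not (rare).
"""

from rarehnc import decode, extract_adicap, load_adicap_dictionary

report = """Examen anatomopathologique.
Code ADICAP : BHSI7040
Second prélèvement, ADICAP : PILA7092."""

dictionary = load_adicap_dictionary()
for code in extract_adicap(report, dictionary):
    d = decode(code, dictionary)
    print(
        f"{code.raw}: site={d.site_label!r} malignant={d.is_malignant} "
        f"hnc={d.is_hnc} rare_topo={d.is_rare_topography} scc={d.is_scc}"
    )

# BHSI7040: a malignant adenocarcinoma of the maxillary sinus -> both a rare
# topography (sinus) and a rare histology (non-squamous) signal.
# PILA7092: a malignant squamous-cell carcinoma of the larynx -> common on
# both axes, so it contributes HNC membership but no rarity evidence.
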