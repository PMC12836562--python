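# Synthetic ADICAP decoding dictionary (fixture).
#
# ADICAP codes are 8-character strings carried by French pathology reports;
# four 2-character fields describe the sample type, the sample site, the
# benign/malignant behaviour and the tumour histology.  This dictionary is a
# small, documented stand-in for the official ADICAP thesaurus (which is not
# redistributable here): the site inventory covers the REFCOR rare
# topographies (salivary glands, sinus, nasal fossa, nasopharynx, middle
# ear), the common HNC sites, and a few non-HNC sites; the histology
# inventory covers squamous-cell carcinoma (SCC, the common type) and the
# main non-squamous classes.  All classification logic is dictionary-driven,
# so swapping in the true thesaurus is a data change only.

# Positional layout of the four 2-character fields within the 8 characters.
field_order: [sample_type, site, behaviour, histology]

# Regex locating codes inside report text: an "ADICAP" cue followed by the
# 8-character token, or a standalone code line.  {code} is the token slot.
cue_pattern: "(?i)\\bADICAP\\b[\\s:.\\-]*"
allow_standalone_line: true

sample_types:
  BH: "biopsie"
  PI: "pièce opératoire"
  CY: "cytologie"
  PO: "ponction"

sites:
  # REFCOR rare topographies
  PA: {label: "parotide", is_hnc: true, is_rare_topography: true}
  GS: {label: "glande sous-maxillaire", is_hnc: true, is_rare_topography: true}
  GA: {label: "glande salivaire accessoire", is_hnc: true, is_rare_topography: true}
  SI: {label: "sinus maxillaire", is_hnc: true, is_rare_topography: true}
  SE: {label: "sinus ethmoïdal", is_hnc: true, is_rare_topography: true}
  FN: {label: "fosse nasale", is_hnc: true, is_rare_topography: true}
  CV: {label: "cavum (nasopharynx)", is_hnc: true, is_rare_topography: true}
  OM: {label: "oreille moyenne", is_hnc: true, is_rare_topography: true}
  # common HNC topographies
  OR: {label: "oropharynx", is_hnc: true, is_rare_topography: false}
  LA: {label: "larynx", is_hnc: true, is_rare_topography: false}
  HP: {label: "hypopharynx", is_hnc: true, is_rare_topography: false}
  OC: {label: "cavité orale", is_hnc: true, is_rare_topography: false}
  LG: {label: "langue", is_hnc: true, is_rare_topography: false}
  AM: {label: "amygdale", is_hnc: true, is_rare_topography: false}
  LV: {label: "lèvre", is_hnc: true, is_rare_topography: false}
  # non-HNC sites
  PU: {label: "poumon", is_hnc: false, is_rare_topography: false}
  CN: {label: "côlon", is_hnc: false, is_rare_topography: false}
  SN: {label: "sein", is_hnc: false, is_rare_topography: false}
  PR: {label: "prostate", is_hnc: false, is_rare_topography: false}
  ES: {label: "estomac", is_hnc: false, is_rare_topography: false}

behaviours:
  "00": {label: "tissu normal", is_malignant: false}
  "10": {label: "lésion bénigne", is_malignant: false}
  "70": {label: "tumeur maligne primitive", is_malignant: true}
  "75": {label: "tumeur maligne secondaire", is_malignant: true}

histologies:
  "92": {label: "carcinome épidermoïde", is_scc: true}
  "40": {label: "adénocarcinome", is_scc: false}
  "42": {label: "carcinome adénoïde kystique", is_scc: false}
  "43": {label: "carcinome mucoépidermoïde", is_scc: false}
  "30": {label: "carcinome neuroendocrine", is_scc: false}
  "59": {label: "esthésioneuroblastome", is_scc: false}
  "60": {label: "sarcome", is_scc: false}
  "67": {label: "lymphome", is_scc: false}
  "77": {label: "mélanome muqueux", is_scc: false}
  "01": {label: "tissu sain", is_scc: false}

# Whether rare-topography ADICAP evidence additionally requires a malignant
# behaviour field (the cohort is cancer patients, so the default is true).
require_malignant_for_topo: true
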