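# French lexicon (fixture) for mining histology and topography mentions from
# pathology-report free text.
#
# Matching is case- and accent-insensitive: every pattern is written in
# lowercase without diacritics and is applied to a folded copy of the text
# (same length, so spans are valid in the original).  Histology entries with
# is_rare: false are the common squamous-cell carcinoma (SCC) surface forms,
# which the REFCOR definition excludes from rare-histology status; topography
# entries with is_rare: false are the common upper-aerodigestive-tract sites.
# This inventory approximates the rare-HNC definitions (salivary glands,
# sinus, nasal fossa, nasopharynx, middle ear; any non-SCC histology); it is
# hot-swappable and makes no claim of exhaustiveness.

entries:
  # ---- histology, rare (non-squamous) ----
  - {pattern: "\\badenocarcinomes?\\b", category: histology, label: adenocarcinome, is_rare: true}
  - {pattern: "\\bcarcinomes? adenoides? kystiques?\\b", category: histology, label: carcinome_adenoide_kystique, is_rare: true}
  - {pattern: "\\bcarcinomes? muco-?epidermoides?\\b", category: histology, label: carcinome_mucoepidermoide, is_rare: true}
  - {pattern: "\\bcarcinomes? neuroendocrines?\\b", category: histology, label: carcinome_neuroendocrine, is_rare: true}
  - {pattern: "\\bmelanomes? muqueux\\b", category: histology, label: melanome_muqueux, is_rare: true}
  - {pattern: "\\besthesioneuroblastomes?\\b", category: histology, label: esthesioneuroblastome, is_rare: true}
  - {pattern: "\\b(?:angio|osteo|rhabdomyo|leiomyo)?sarcomes?\\b", category: histology, label: sarcome, is_rare: true}
  - {pattern: "\\blymphomes?\\b", category: histology, label: lymphome, is_rare: true}
  - {pattern: "\\bcarcinomes? a cellules acineuses\\b", category: histology, label: carcinome_cellules_acineuses, is_rare: true}
  - {pattern: "\\bplasmocytomes?\\b", category: histology, label: plasmocytome, is_rare: true}
  # ---- histology, common (SCC; matched so it is never mistaken for rare) ----
  - {pattern: "\\bcarcinomes? epidermoides?\\b|\\bcarcinomes? malpighiens?\\b", category: histology, label: carcinome_epidermoide, is_rare: false}
  # ---- topography, rare (REFCOR) ----
  - {pattern: "\\bparotides?\\b|\\bparotidiens?(?:ne)?\\b", category: topography, label: parotide, is_rare: true}
  - {pattern: "\\bglandes? sous-?maxillaires?\\b|\\bglandes? subman?dibulaires?\\b", category: topography, label: glande_sous_maxillaire, is_rare: true}
  - {pattern: "\\bglandes? salivaires?(?: accessoires?)?\\b", category: topography, label: glande_salivaire, is_rare: true}
  - {pattern: "\\bsinus maxillaires?\\b", category: topography, label: sinus_maxillaire, is_rare: true}
  - {pattern: "\\bsinus ethmoidal\\b|\\bethmoides?\\b", category: topography, label: sinus_ethmoidal, is_rare: true}
  - {pattern: "\\bfosses? nasales?\\b", category: topography, label: fosse_nasale, is_rare: true}
  - {pattern: "\\bcavum\\b|\\b(?:naso|rhino)pharynx\\b", category: topography, label: nasopharynx, is_rare: true}
  - {pattern: "\\boreille moyenne\\b", category: topography, label: oreille_moyenne, is_rare: true}
  # ---- topography, common HNC ----
  - {pattern: "\\blarynx\\b|\\blarynge(?:e|es)?\\b", category: topography, label: larynx, is_rare: false}
  - {pattern: "\\boropharynx\\b", category: topography, label: oropharynx, is_rare: false}
  - {pattern: "\\bhypopharynx\\b", category: topography, label: hypopharynx, is_rare: false}
  - {pattern: "\\bcavite (?:orale|buccale)\\b", category: topography, label: cavite_orale, is_rare: false}
  - {pattern: "\\bamygdales?\\b", category: topography, label: amygdale, is_rare: false}
  - {pattern: "\\blangue\\b", category: topography, label: langue, is_rare: false}
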