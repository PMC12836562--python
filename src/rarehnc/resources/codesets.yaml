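# ICD-10 code-set configuration for head-and-neck-cancer (HNC) phenotyping.
#
# Codes are matched dot-free, uppercase, by prefix by default: a claim code
# matches a set entry if it equals it or extends it ("C110" matches "C11").
#
# hnc_codes is a documented default (lip / oral cavity / pharynx C00-C14 plus
# nasal cavity / sinus / larynx C30-C32); site-specific deployments should
# replace it with their local HNC list.  rare_topography_codes is the
# rare-topography claim list (parotid C07, other salivary glands C08,
# nasopharynx C11, bone incl. middle ear C41, nasal cavity C300, middle ear
# C301, accessory sinuses C31).  Codes in the rare list count as HNC-relevant
# even when outside hnc_codes (C41).

hnc_codes:
  - C00
  - C01
  - C02
  - C03
  - C04
  - C05
  - C06
  - C07
  - C08
  - C09
  - C10
  - C11
  - C12
  - C13
  - C14
  - C30
  - C31
  - C32

rare_topography_codes:
  - C07
  - C08
  - C11
  - C41
  - C300
  - C301
  - C31

# Diagnosis positions accepted for HNC-cohort membership (narrow rule) ...
hnc_positions: [primary, related]
# ... and for rare-topography evidence (wide rule).
rare_topo_positions: [primary, related, associated]

# Prefix matching (default) versus exact code equality.
exact_match: false
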