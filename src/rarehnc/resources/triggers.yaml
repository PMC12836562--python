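# Qualifier triggers (fixture) for negation, hypothesis and medical-history
# detection in French pathology-report text.
#
# Scoping is ConText-style: a mention acquires qualifier q when a q-trigger
# occurs in the SAME sentence, on the trigger's configured side of the
# mention (forward = trigger precedes the mention, backward = trigger
# follows it), with at most `scope` whitespace tokens between them.
# Patterns are lowercase, unaccented, applied to folded text.

default_scope: 8

negation:
  - {pattern: "\\bpas d[e']\\s?", direction: forward}
  - {pattern: "\\babsence d[e']\\s?", direction: forward}
  - {pattern: "\\bsans\\b", direction: forward}
  - {pattern: "\\baucune?\\b", direction: forward}
  - {pattern: "\\bnegatif pour\\b", direction: forward}
  - {pattern: "\\bexclu[te]?s?\\b", direction: backward, scope: 5}
  - {pattern: "\\belimine[es]?\\b", direction: backward, scope: 5}

hypothesis:
  - {pattern: "\\bsuspicion d[e']\\s?", direction: forward}
  - {pattern: "\\bsuspect[e]? d[e']\\s?", direction: forward}
  - {pattern: "\\bevoqu(?:e|ant|er)\\b", direction: forward}
  - {pattern: "\\bevocateur d[e']\\s?", direction: forward}
  - {pattern: "\\bcompatible avec\\b", direction: forward}
  - {pattern: "\\bpourrait\\b", direction: forward}
  - {pattern: "\\bprobable\\b", direction: backward, scope: 3}
  - {pattern: "\\bpossible\\b", direction: backward, scope: 3}

history:
  - {pattern: "\\bantecedents? d[e']\\s?", direction: forward}
  - {pattern: "\\batcd d[e']\\s?", direction: forward}
  - {pattern: "\\bhistoire d[e']\\s?", direction: forward}
  - {pattern: "\\bancien(?:ne)?\\b", direction: forward, scope: 4}
  - {pattern: "\\bopere[e]? en (?:19|20)\\d{2} pour\\b", direction: forward}
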