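# Default NegEx trigger and contextual-cue lexicon.
# The eight cue stems printed in the published filter description
# (no, rule out, deny, unremarkable; risk, concern, worry, evaluation)
# are mandatory; the remainder are repo defaults standing in for the
# unpublished customized list.  All entries lowercase.
negex_pre:
  - "no"
  - "not"
  - "without"
  - "denies"
  - "denied"
  - "deny"
  - "no evidence of"
  - "rule out"
  - "ruled out"
  - "negative for"
  - "free of"
negex_post:
  - "unlikely"
  - "was ruled out"
  - "is ruled out"
scope_terminators:
  - "but"
  - "however"
  - "although"
  - "though"
  - "except"
  - "aside from"
sentence_negation_cues:
  - "no"
  - "rule out"
  - "deny"
  - "denies"
  - "denied"
  - "denying"
  - "unremarkable"
  - "negative"
sentence_uncertainty_cues:
  - "risk"
  - "concern"
  - "worry"
  - "worried"
  - "worries"
  - "worrying"
  - "evaluation"
  - "fear"
  - "possible"
  - "possibly"
  - "suspicious"
  - "differential"
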