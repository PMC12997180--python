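# Default hedging-marker lexicon.
# Uncertainty/confidence marker counts are lexicon-dependent, so the lexicon
# in force is always declared; users override it with a file of this shape.
uncertainty:
  - may
  - might
  - possibly
  - possible
  - uncertain
  - cannot rule out
  - unclear
  - suspected
  - consider
  - less likely
confidence:
  - clearly
  - definitive
  - consistent with
  - classic
  - certain
  - pathognomonic
  - strongly suggests
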