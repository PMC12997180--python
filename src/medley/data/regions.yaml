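# Country / territory aliases mapped to the four provenance buckets.
# Loose vendor metadata often names a country; grouping uses the buckets.
US:
  - united states
  - united states of america
  - america
Europe:
  - france
  - germany
  - united kingdom
  - uk
  - great britain
  - england
  - sweden
  - norway
  - denmark
  - finland
  - netherlands
  - spain
  - italy
  - poland
  - switzerland
  - austria
  - belgium
  - ireland
  - portugal
  - czech republic
  - greece
China:
  - prc
  - people's republic of china
  - hong kong
Other:
  - canada
  - israel
  - japan
  - south korea
  - korea
  - india
  - singapore
  - taiwan
  - australia
  - new zealand
  - brazil
  - mexico
  - russia
  - united arab emirates
  - saudi arabia
  - south africa
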