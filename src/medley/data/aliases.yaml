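# Starter synonym table: canonical diagnosis -> known aliases.
# Entries are folded through the same canonicalization as candidate labels,
# so case and punctuation do not matter here.
familial mediterranean fever:
  - fmf
  - recurrent polyserositis
mcardle disease:
  - glycogen storage disease v
  - glycogen storage disease type v
  - myophosphorylase deficiency
wilsons disease:
  - hepatolenticular degeneration
behcets disease:
  - behcet syndrome
  - adamantiades behcet disease
dementia with lewy bodies:
  - lewy body dementia
  - dlb
iga nephropathy:
  - bergers disease
  - berger disease
hemochromatosis:
  - hereditary hemochromatosis
  - iron overload disease
acute porphyria:
  - acute intermittent porphyria
sarcoidosis:
  - besnier boeck schaumann disease
parkinsons disease:
  - paralysis agitans
myocardial infarction:
  - heart attack
  - mi
deep vein thrombosis:
  - dvt
congestive heart failure:
  - chf
  - heart failure
post-traumatic stress disorder:
  - ptsd
g6pd deficiency:
  - glucose-6-phosphate dehydrogenase deficiency
hiv/aids:
  - aids
  - hiv
  - acquired immunodeficiency syndrome
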