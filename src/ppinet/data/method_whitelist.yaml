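# Default PSI-MI detection methods accepted as reliable experimental
# validation. This is a documented stand-in covering the common
# experimental families; override with --whitelist to match a specific
# curation policy.
accepted:
  - "MI:0004"   # affinity chromatography technology
  - "MI:0006"   # anti bait coimmunoprecipitation
  - "MI:0007"   # anti tag coimmunoprecipitation
  - "MI:0018"   # two hybrid
  - "MI:0019"   # coimmunoprecipitation
  - "MI:0030"   # cross-linking study
  - "MI:0047"   # far western blotting
  - "MI:0055"   # fluorescent resonance energy transfer
  - "MI:0077"   # nuclear magnetic resonance
  - "MI:0089"   # protein array
  - "MI:0096"   # pull down
  - "MI:0107"   # surface plasmon resonance
  - "MI:0114"   # x-ray crystallography
  - "MI:0397"   # two hybrid array
  - "MI:0398"   # two hybrid pooling approach
  - "MI:0399"   # two hybrid fragment pooling approach
  - "MI:0676"   # tandem affinity purification
  - "MI:1112"   # two hybrid prey pooling approach
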