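# Fusion-dominated event preset: fissions allowed but expensive,
# encoding the directional hypothesis (chromosome number decreases,
# biarmed count increases, via fusions and inversions).
costs:
  cF: 1
  tF: 1
  Inv: 1
  fission: 3
enabled: [cF, tF, Inv, fission]
n_max: 30
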