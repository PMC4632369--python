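# Simulation used by the README worked example.
seed: 7
noise_reads: 40
families:
  - amino_acid: Gly
    anticodon: GCC
    multiplicity: 2
    tdrs:
      - {region: mature, span: [1, 32], count: 900}
      - {region: mature, span: [1, 32], count: 200, error: del1, error_pos: 9}
  - amino_acid: Val
    anticodon: CAC
    tdrs:
      - {region: mature, span: [48, 76], count: 450}
  - amino_acid: His
    anticodon: GTG
    tdrs:
      - {region: pre, span: [114, 136], count: 250}
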