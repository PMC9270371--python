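# Canonical interchange dialect: the package's own CSV schema.
name: canonical
score_direction: higher_better
position_base: 1
column_map:
  sequence_a: sequence_a
  sequence_b: sequence_b
  protein_a: protein_a
  protein_b: protein_b
  position_a: position_a
  position_b: position_b
  site_a: site_a
  site_b: site_b
  score: score
  link_type: link_type
  spectrum_ref: spectrum_ref
decoy:
  type: column
  column: is_decoy
  true_values: ["true", "1", "yes"]
link_type_map:
  crosslink: [crosslink, xl, inter, intra]
  deadend: [deadend, dead-end, monolink, mono-link]
  looplink: [looplink, loop-link, loop]
  linear: [linear, single, common]
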