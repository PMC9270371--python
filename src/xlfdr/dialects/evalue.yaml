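# Example lower-better dialect: e-value-like scores, decoys flagged by a
# protein accession prefix, 0-based peptide positions.  Exercises every
# normalization path; edit a copy to match a real engine's export.
name: evalue
score_direction: lower_better
position_base: 0
column_map:
  sequence_a: PepSeq1
  sequence_b: PepSeq2
  protein_a: Protein1
  protein_b: Protein2
  position_a: PepPos1
  position_b: PepPos2
  site_a: LinkPos1
  site_b: LinkPos2
  score: EValue
  link_type: LinkType
  spectrum_ref: Scan
decoy:
  type: protein_prefix
  prefix: DECOY_
link_type_map:
  crosslink: [cross-link, crosslink]
  deadend: [mono-link, deadend]
  looplink: [loop-link, looplink]
  linear: [linear]
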