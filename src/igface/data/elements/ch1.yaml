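# Coarse-graining elements for the IgG1 CH1 domain (EU numbering).
# Reconstructed C1-set topology; interface-relevant positions: S183 in strand
# E, F170 in strand D, S181 in strand E edge. Regenerable with
# igface.elements.assign_strands on a reference Fab structure.
domain_kind: CH1
elements:
  A:  [[121, 128]]
  AB: [[129, 136]]
  B:  [[137, 144]]
  BC: [[145, 150]]
  C:  [[151, 158]]
  CD: [[159, 166]]
  D:  [[167, 173]]
  DE: [[174, 179]]
  E:  [[180, 188]]
  EF: [[189, 195]]
  F:  [[196, 203]]
  FG: [[204, 207]]
  G:  [[208, 214]]
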