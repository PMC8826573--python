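# Coarse-graining elements for the kappa light-chain constant domain CL
# (EU light-chain numbering). Reconstructed C1-set topology; V133 in strand B,
# S176 in strand E, F116 at the A-strand edge. Regenerable with
# igface.elements.assign_strands on a reference Fab structure.
domain_kind: CL-kappa
elements:
  A:  [[111, 118]]
  AB: [[119, 126]]
  B:  [[127, 134]]
  BC: [[135, 140]]
  C:  [[141, 148]]
  CD: [[149, 156]]
  D:  [[157, 163]]
  DE: [[164, 169]]
  E:  [[170, 178]]
  EF: [[179, 187]]
  F:  [[188, 195]]
  FG: [[196, 199]]
  G:  [[200, 207]]
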