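# Coarse-graining elements for the VH domain (Kabat-style numbering).
# The V-set fold has 9 strands (A, B, C, C', C'', D, E, F, G); to stay within
# the 7-letter coarse-graining label set the short C'/C'' strands flanking
# CDR2 are folded into the CD segment. A simplification, documented in
# docs/methods.md.
domain_kind: VH
elements:
  A:  [[4, 11]]
  AB: [[12, 16]]
  B:  [[17, 25]]
  BC: [[26, 35]]
  C:  [[36, 45]]
  CD: [[46, 65]]
  D:  [[66, 71]]
  DE: [[72, 74]]
  E:  [[75, 82]]
  EF: [[83, 88]]
  F:  [[89, 96]]
  FG: [[97, 102]]
  G:  [[103, 112]]
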