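# Coarse-graining elements for the VL domain (Kabat-style numbering).
# As for VH, the short C'/C'' strands flanking CDR2 are folded into the CD
# segment to stay within the 7-letter label set.
domain_kind: VL
elements:
  A:  [[4, 11]]
  AB: [[12, 15]]
  B:  [[16, 24]]
  BC: [[25, 33]]
  C:  [[34, 43]]
  CD: [[44, 65]]
  D:  [[66, 71]]
  DE: [[72, 74]]
  E:  [[75, 81]]
  EF: [[82, 87]]
  F:  [[88, 95]]
  FG: [[96, 100]]
  G:  [[101, 107]]
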