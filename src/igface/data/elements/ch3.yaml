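# Coarse-graining elements for the IgG1 CH3 domain (EU numbering).
# Beta-strands A-G of the C1-set immunoglobulin fold plus connecting loops.
# Reconstructed from Ig-fold topology constraints: Y407 sits centrally in
# strand E, T366/L368 in strand B, E356/E357 in the AB loop, K439 in strand G,
# K392 in strand D, D399 in the DE loop. Regenerable with
# igface.elements.assign_strands on a reference CH3 dimer structure.
domain_kind: CH3
elements:
  A:  [[342, 349]]
  AB: [[350, 358]]
  B:  [[359, 368]]
  BC: [[369, 375]]
  C:  [[376, 383]]
  CD: [[384, 389]]
  D:  [[390, 396]]
  DE: [[397, 403]]
  E:  [[404, 412]]
  EF: [[413, 420]]
  F:  [[421, 428]]
  FG: [[429, 435]]
  G:  [[436, 443]]
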