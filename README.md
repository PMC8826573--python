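# igface

Interface characterization of paired immunoglobulin-like domains.

Antibody engineering — knobs-into-holes CH3 heterodimers, charge-pair
CH1-CL designs, bispecific formats — lives on a detailed understanding of
how two Ig domains pack against each other. `igface` implements the
analyses used to compare such interfaces across structures and simulation
ensembles:

* **Typed interdomain contacts.** Per frame, contacts between domain *a*
  (CL, or CH3 domain A) and domain *b* (CH1, or CH3 domain B) are detected
  geometrically and classified as hydrogen bond (donor–acceptor ≤ 3.5 Å,
  D–H···A ≥ 110°), salt bridge (cation N to anion O ≤ 4.0 Å), hydrophobic
  (apolar C pair ≤ 4.5 Å) or van der Waals (r₁+r₂+0.5 Å), with the more
  specific class winning per atom pair. The **occurrence ratio** of a
  residue pair is the fraction of frames in which it is in contact.
* **Coarse-grained contact maps.** Residues are grouped into the β-strands
  A–G and loops (AB … FG) of the Ig fold; the element-pair ratio is the
  frame-union existence statistic. Interface classes are compared via
  per-pair means ± SEM (sample sd / √n over systems) and signed difference
  maps normalized by the most frequent contact in either class, plus
  per-residue duration-weighted "open-book" scores written to the B-factor
  column.
* **Interdomain orientation coordinates.** Each domain's first principal
  axis of inertia is aligned to ẑ and the centre axis to x̂, giving a
  reference that is Kabsch-aligned onto every frame. Six measures result:
  the torsion AB between the A1/C and B1/C planes, four tilts
  (AC1, AC2, BC1, BC2) and the centre distance dC — the same coordinates
  reported as HL/LC1/… for Fv pairs and cHL/cLC1/… for CH1-CL. Angle
  distributions come out as Gaussian KDEs; Cα RMSD superposition and RMSF
  round out the geometry toolkit.
* **Interdomain electrostatics.** Per-frame Coulomb sums
  E = k·Σ qᵢqⱼ/(ε·rᵢⱼ) (k = 332.0636 kcal·Å/mol·e²) between the two
  domains, with cutoff and dielectric exposed, from PQR charges or a coarse
  formal-charge table.
* **Synthetic ensembles with ground truth.** Idealized β-sandwich domains
  are assembled at an exact requested orientation and expanded into noisy
  frame ensembles with contacts planted at known occurrence ratios — every
  random draw is logged, so recovery can be checked against what was
  actually planted.

Structures are read from PDB files (multi-model PDB doubles as the
trajectory format); author residue numbering (EU numbering for constant
domains) is preserved end to end.

## Worked example

```python
import numpy as np
from igface import synthetic, contacts, orientation, structio
from igface.coarse import coarse_grain

# 2,000-frame synthetic ensemble: two 7-strand sandwich domains at a 90°
# torsion, 0.3 Å coordinate noise, one salt bridge planted at ratio 0.65
spec = synthetic.SynthSpec(n_frames=2000, noise_sigma=0.3, seed=11)
traj, truth = synthetic.synthesize(spec)

roles = contacts.assign_chem_roles(traj.topology)
idx_a = structio.select_domain(traj.topology, truth.selections["a"])
idx_b = structio.select_domain(traj.topology, truth.selections["b"])
records = contacts.contacts_over_trajectory(traj, roles, idx_a, idx_b)

(ra, rb, kind), presence = next(iter(truth.contact_presence.items()))
ratio = contacts.contact_ratio(records, (ra, rb), traj.frame_count, kind)
print(f"planted {kind} {ra[0]}:{ra[1]} - {rb[0]}:{rb[1]}: "
      f"recovered ratio {ratio:.4f} (ground truth {presence.mean():.4f})")

tables = coarse_grain(records, truth.element_maps["a"], truth.element_maps["b"],
                      traj.frame_count)
ea = truth.element_maps["a"].label_of(ra)
eb = truth.element_maps["b"].label_of(rb)
print(f"element pair a_{ea} - b_{eb}: ratio {tables[kind].ratio(ea, eb):.4f}")

ref = orientation.build_reference(traj.topology, truth.selections["a"],
                                  truth.selections["b"])
series = orientation.measure_trajectory(traj, ref)
print(f"AB torsion: {series['AB'].mean():.2f} +/- {series['AB'].std(ddof=1):.2f} deg "
      f"(planted {truth.measures['AB']:.0f})")
print(f"dC: {series['dC'].mean():.2f} +/- {series['dC'].std(ddof=1):.2f} A")
```

prints

```
planted saltbridge A:11 - B:20: recovered ratio 0.6600 (ground truth 0.6600)
element pair a_B - b_C: ratio 0.6600
AB torsion: 90.00 +/- 0.38 deg (planted 90)
dC: 29.51 +/- 0.04 A
```

The detected occurrence ratio equals the logged ground truth exactly — the
planting geometry keeps the pair unambiguous under noise — and coarse
graining maps it onto the strand pair a_B–b_C. The torsion is recovered at
the planted 90° with sub-degree scatter; the mean dC sits 0.5 Å under the
planted 30 Å because the planted salt-bridge side chain stretches across
the gap and drags the domain-a centre of mass slightly towards b.

Command-line equivalents: `igface synth`, `igface contacts`,
`igface orient`, `igface energy`, `igface diffmap`, `igface openbook`
(each writes its tables plus a reproducibility manifest; see `--help`).

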