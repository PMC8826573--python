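# Methods

## Scope and data model

The package analyses the interface between two immunoglobulin-like domains
— constant-domain pairs (CH3-CH3 homo/heterodimers, CH1-CL) and variable
pairs (VH-VL) — given either a single structure or a frame ensemble.
Multi-model PDB is the trajectory container: model 1 supplies the topology
and each MODEL block one frame, all with identical atom counts. Author
residue numbering is preserved everywhere; for IgG constant domains this is
EU numbering, so positions such as 366, 407 or 439 keep their conventional
identities. Altloc records collapse to the highest-occupancy conformer
(ties to the lexicographically first altloc id). Waters and HETATM records
are excluded from domain selections unless explicitly listed: the analyses
concern protein–protein interfaces. The two domains of a pair are labelled
*a* (CL, or CH3 domain A) and *b* (CH1, or CH3 domain B).

## Contact detection

Atoms receive chemical roles from a packaged table over the standard amino
acids (plus common MD protonation variants): hydrogen-bond donors are N/O
with a bound hydrogen, acceptors are lone-pair-bearing N/O, cations are the
Lys/Arg/His(+) side-chain nitrogens, anions the Asp/Glu carboxylate oxygens
and C-terminal OXT, and apolar carbons are carbons with no bonded N/O.
Bound hydrogens are found geometrically (same residue, within 1.25 Å).

Four channels are evaluated per interdomain atom pair per frame, with the
most specific satisfied channel winning (salt bridge > hydrogen bond >
hydrophobic > van der Waals), so no pair is double-counted:

| channel      | predicate                                   | default |
|--------------|---------------------------------------------|---------|
| salt bridge  | cation N – anion O distance                 | ≤ 4.0 Å |
| hydrogen bond| donor–acceptor distance, D–H···A angle      | ≤ 3.5 Å, ≥ 110° |
| hydrophobic  | apolar C – apolar C distance                | ≤ 4.5 Å |
| van der Waals| heavy-atom distance ≤ r₁ + r₂ + slack       | slack 0.5 Å |

All thresholds are configuration, not constants: they follow the widely
used GetContacts defaults, and deployments that need other criteria set
them per run. Structures without hydrogens (the normal X-ray case) use a
heavy-atom fallback: the angle test is skipped and the donor set widens to
all polar N/O. The fallback is on by default for single structures and off
for trajectories whose topology carries hydrogens. Hydrogen bonds carry a
subtype tag (sidechain/sidechain, sidechain/backbone, backbone/backbone).
Aromatic stacking (e.g. the Tyr–Tyr pair at the CH3 interface centre) has
no dedicated detector; it is captured by the hydrophobic/vdW channels,
which reports its persistence but not its π character. No periodic-boundary
imaging is applied: inputs are assumed to be whole molecules, since
multi-model PDB carries no reliable box.

The **occurrence ratio** of a residue pair (optionally per channel) is the
fraction of frames containing at least one matching record; several atom
pairs in one frame count once. Ratios are invariant under frame reordering
and lie in [0, 1] by construction.

## Coarse graining and class comparison

Residues map onto the Ig-fold elements — β-strands A–G and the loops named
by their flanking strands — either from packaged canonical annotations per
domain kind (CH3, CH1, CL-κ, CL-λ, VH, VL; YAML files of author-numbering
ranges) or from a built-in strand detector. The detector finds backbone
hydrogen bonds with the Kabsch–Sander electrostatic criterion
(E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5; amide H taken explicit when present, else placed 1 Å from N
opposite the preceding carbonyl), marks residues in mutual or offset
bridge patterns, absorbs single-residue bulges, and labels the resulting
segments A–G in sequence order. It refuses fewer than 2 or more than 7
segments, deferring to manual annotation; constant domains have 7 strands
(a 3-stranded sheet packed against a 4-stranded one), variable domains 9,
which the packaged VH/VL maps accommodate by folding the short C′/C″
strands into the CD segment — a deliberate simplification of the V-set
topology to keep one label alphabet across domain kinds.

The packaged canonical maps are reconstructions from the Ig-fold
literature anchored at conserved interface positions (Y407 central in
strand E, E356/E357 in the AB loop, K439 in strand G, T366 in strand B,
EU numbering); they are regenerable by running the strand detector on
reference crystal structures and should be refreshed that way when the
reference PDB entries are at hand. Exact strand boundaries (±1–2 residues)
are the least certain part of the annotation.

The element-pair ratio is the frame union over member residue pairs — an
existence statistic matching what a flareplot edge encodes — not a sum of
per-residue ratios; it therefore dominates each constituent ratio and
never exceeds 1. Class summaries average these matrices over member
systems with SEM = sample sd/√n (0 at n = 1); element pairs absent from a
system count as ratio 0, because the absence of a contact is an
observation, not missing data. Difference maps are
(mean₁ − mean₂)/max(both means): antisymmetric under class swap, bounded
in [−1, 1], undefined (error) when both classes are empty. Open-book
scores sum, per residue, the occurrence ratios of its distinct interdomain
partners — number weighted by duration — and are exported in the B-factor
column (clipped with a warning outside the %6.2f range) plus a TSV.
Both pairwise matrices and per-element marginals are produced, since
barplot-style summaries may aggregate either way.

## Interdomain orientation coordinates

A reference coordinate system is built from a reference structure and two
domain selections. Per domain: the centre of mass and inertia tensor are
computed over heavy atoms, mass-weighted (a `ca` mode uses Cα atoms
instead — the atom set is configuration because conventions differ between
tools); the principal axis is the eigenvector of the smallest inertia
eigenvalue, its sign fixed to point along the first→last Cα vector (a
deterministic resolution of the eigenvector's ± ambiguity); the domain is
rotated so this axis is +ẑ and then about ẑ so the projected centre axis
(towards the partner domain) points along +x̂. Near-degenerate inertia
spectra (relative gap < 1e−6) and centre axes within 1° of the principal
axis are rejected as ill-posed.

To measure a frame, each domain's reference Cα set is Kabsch-aligned onto
the frame (proper rotation enforced by determinant correction; RMSD > 5 Å
triggers a reference-mismatch warning) and the rotations are applied to
the unit vectors: A1/B1 are the images of ẑ, A2/B2 of ŷ. With Ĉ the unit
a→b centre axis: AC1 = ∠(A1, Ĉ), AC2 = ∠(A2, Ĉ), BC1 = ∠(B1, −Ĉ),
BC2 = ∠(B2, −Ĉ), dC = |centre distance|, and AB is the dihedral between
the components of A1 and B1 perpendicular to Ĉ, signed right-handed about
the a→b axis in (−180°, 180°]. Measuring the b-domain tilts against −Ĉ
makes a symmetric homodimer give AC1 ≈ BC1 — a convention choice, as is
the torsion sign; both are documented rather than claimed canonical, and
an absolute-value view is a one-liner on the output table. The measures
are invariant under global rigid motion of a frame, a planted rotation
about the centre axis appears additively in AB alone, and a planted
centre-axis translation appears in dC alone.

Per-frame series carry columns (AB, AC1, AC2, BC1, BC2, dC), renamed to
the HL/LC1/… convention for Fv pairs and cHL/cLC1/… for CH1-CL on request.
Torsion distributions use a Gaussian KDE (Silverman bandwidth by default,
absolute bandwidth in degrees optional) on a 0.1° grid spanning the
samples ± 4 bandwidths; zero-variance inputs are rejected rather than
producing a delta spike. RMSF superposes every frame onto a chosen
reference frame over the selection's Cα atoms and reports per-residue RMS
displacement about the time-average position.

## Electrostatics

Interdomain electrostatic energy per frame is the bare Coulomb double sum
over the two selections, k = 332.0636 kcal·Å/(mol·e²), with a 12 Å cutoff
and ε = 1 by default (both exposed; the cutoff can be disabled). There is
no distance-dependent dielectric, no vdW term and no solvent screening:
this is the simple pairwise electrostatic component of a linear
interaction energy, useful for comparing interfaces, not a free energy.
Charges come from a PQR file matched by (chain, residue, atom name) — a
chain-less PQR matches single-chain structures — or from a coarse
formal-charge table (Asp/Glu −1 split over the carboxylate oxygens,
Lys +1 on NZ, Arg +1 split over NH1/NH2) when only titratable-group
charges are wanted. Interdomain pairs closer than 0.5 Å abort the
computation as corrupt input. Trajectory summaries report the mean and
sample standard deviation. Because the cutoff, dielectric and charge set
are all choices, absolute values are comparable only within one
configuration.

## Synthetic ensembles

The generator exists to give every analysis a ground truth. A toy domain
is an idealized antiparallel β-sandwich: poly-alanine strands at 4.8 Å
spacing and 3.4 Å Cα rise, carbonyls and explicit amide hydrogens pointing
across the sheet so the Kabsch–Sander ladder is real, two sheets 10 Å
apart, 2-residue loops, and three outer-face residues mutated to Lys, Glu
and Leu (sites seed-chosen) so that every contact channel has partners.
Two domains are assembled at an exactly requested orientation by rotating
each domain's sign-fixed principal axis onto target directions derived in
closed form from the requested torsion, tilts and centre distance; the
resulting complex measures back the request to machine precision (the
AC2/BC2 tilts are 90° by construction of the reference frame, so only
AC1/BC1 are free). Interdomain clashes under 2 Å reject the geometry.

Ensembles add isotropic Gaussian coordinate noise (default σ = 0.3 Å) to
every atom, then toggle planted contacts: per frame, a Bernoulli draw at
the target ratio decides whether the planted side chain is re-posed so its
tip atom sits at contact distance from the partner tip (3.5 Å salt bridge,
2.9 Å N···O hydrogen bond with the hydrogen collinear, 4.0 Å hydrophobic,
3.5 Å C···O vdW) or far beyond threshold+1 Å (margins sized so secondary
atoms such as OE2/CD2 cannot slip under a threshold either). The side
chain extends from the tip back towards its own backbone, choosing among a
few deterministic directions the one clearest of the partner domain, so
plants never create sub-0.5 Å clashes. Backbone atoms are never moved by
planting, keeping the orientation ground truth intact; the planted side
chain does shift the domain's centre of mass slightly (visible as a
sub-Å dC offset). All draws come from one generator seeded per spec and
are logged in the ground truth, so "recovered ratio equals realized
fraction" is testable exactly. Defaults mirror the targeted study
conditions: 7-strand domains, 90° torsion, 30 Å centre distance, 10,000
frames, σ = 0.3 Å, one salt bridge at ratio 0.65 (the occurrence of the
conserved long-lived class of interface hydrogen bonds/salt bridges).

What the generator does *not* emulate: real side-chain rotamers and
packing, correlated domain motions, solvent, and sequence context. Passing
recovery tests therefore demonstrates the correctness of the measurement
chain (detection → aggregation → statistics; reference building →
alignment → measures), not robustness to the conformational heterogeneity
of real MD ensembles.

## Numerical choices and edge cases

* Kabsch superposition via SVD with determinant correction; never a
  reflection. Weighted variant used for mass-weighted needs.
* Angle cosines are clipped to [−1, 1] before arccos; torsions use atan2
  and return values in (−180°, 180°], with −180° mapped to +180°.
* SEM uses the n−1 denominator; n = 1 gives SEM 0 by convention.
* KDE integral over its grid is 1 ± 1e−3 (4-bandwidth margins make the
  truncation error negligible at that tolerance).
* Contact detection uses a KD-tree at the largest active threshold and is
  tested for exact agreement with a plain all-pairs evaluation.
* B-factor export clips to the PDB %6.2f field with a warning.
* Problem sizes in the shipped tests and the acceptance script are chosen
  to exercise the stated study conditions where they matter (10,000 frames
  for ratio recovery, 1,000 frames for noisy orientation recovery) and
  compact domains elsewhere; all synthetic systems are a few hundred atoms.

## Known limitations

* The two crystal-structure checks (Cα-RMSD between a CH3-CH3 and a
  CH1-CL dimer; X-ray torsions near 90°/50°) require reference PDB entries
  that are not shipped; the corresponding tests fail until the files are
  supplied under `tests/data/reference/`.
* Canonical element maps are literature reconstructions (see above), not
  frozen output of a secondary-structure run on the reference entries.
* The orientation coordinates are a generalization of the Fv-specific
  consensus-plane convention, not a numerical reimplementation of it;
  values agree in spirit (same six-coordinate design) but not digit for
  digit with tools that hard-code Fv consensus structures.
* No binary trajectory formats in core; multi-model PDB only.
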