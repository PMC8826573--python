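"""Synthetic two-domain complexes with known orientations and contacts.

Stand-in for MD ensembles of paired Ig domains: idealized antiparallel
beta-sandwich "domains" (poly-alanine with a few interface residues mutated
to Lys/Glu/Leu so that every contact channel has partners), assembled at a
requested interdomain orientation, then expanded into a frame ensemble with
isotropic Gaussian coordinate noise and contacts planted to occur in a
specified fraction of frames.  Every random draw is logged in the ground
truth, so recovery of orientations and occurrence ratios can be checked
against what was actually planted.

The geometry is rigid and not physically relaxed; it exists to make the
analysis pipeline testable, not to emulate real dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import STRAND_LABELS, ElementMap
from .orientation import inertia_principal_axis, _rotation_between
from .structio import Atom, DomainSelection, Structure, Trajectory

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "build_toy_domain",
    "toy_element_map",
    "mutated_residues",
    "assemble_complex",
    "synth_trajectory",
    "synthesize",
]

_STRAND_SPACING = 4.8   # Å between neighbouring strands in a sheet
_CA_RISE = 3.4          # Å per residue along a strand
_SHEET_GAP = 10.0       # Å between the two sheets of the sandwich
_LOOP_LEN = 2           # residues per connecting loop

#: tip-atom geometry per planted contact kind: (mover atom on residue_a,
#: partner atom on residue_b, contact distance, separated distance).
#: Separated distances sit well beyond threshold+1 so that secondary atoms
#: (OE2, CD2, ...) of the partner cannot slip under the threshold either.
_PLANT_GEOMETRY = {
    "saltbridge": ("NZ", "OE1", 3.5, 6.6),
    "hbond": ("NZ", "O", 2.9, 6.1),
    "hydrophobic": ("CD1", "CD1", 4.0, 7.1),
    "vdw": ("CD", "O", 3.5, 6.3),
}
_BACKBONE = {"N", "CA", "C", "O"}


@dataclass
class SynthSpec:
    """Study conditions for a synthetic trajectory.

    Defaults mirror the conditions the analyses target: 7-strand constant-
    domain-like sandwiches, a ~90° interdomain torsion as seen for constant-
    domain pairs in crystal structures, 10,000 frames per ensemble, 0.3 Å
    coordinate noise, and one salt bridge planted at the 0.65 occurrence
    ratio of the conserved Y407-T366 class of long-lived interface contacts.
    """

    strands_per_domain: int = 7
    residues_per_strand: int = 6
    torsion_ab: float = 90.0
    tilts: tuple[float, float] = (90.0, 90.0)
    d_c: float = 30.0
    n_frames: int = 10_000
    noise_sigma: float = 0.3
    planted_contacts: list[tuple] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for plant in self.planted_contacts:
            if not 0.0 <= plant[3] <= 1.0:
                raise ValueError(f"target ratio {plant[3]} outside [0, 1]")


@dataclass
class GroundTruth:
    """What was actually planted, logged draw by draw."""

    measures: dict[str, float]
    selections: dict[str, DomainSelection]
    element_maps: dict[str, ElementMap]
    #: (residue_a, residue_b, kind) -> per-frame Bernoulli outcomes
    contact_presence: dict[tuple, np.ndarray] = field(default_factory=dict)

    def realized_ratio(self, key: tuple) -> float:
        presence = self.contact_presence[key]
        return float(presence.mean())


# ---------------------------------------------------------------------------
# toy domain


def _strand_layout(n_strands: int) -> list[tuple[float, float]]:
    """(x, y) origin per strand: two sheets when the sandwich is big enough."""
    n_sheet1 = n_strands if n_strands < 5 else (n_strands + 1) // 2
    layout = []
    for s in range(n_strands):
        if s < n_sheet1:
            layout.append((s * _STRAND_SPACING, 0.0))
        else:
            layout.append(((s - n_sheet1) * _STRAND_SPACING + 2.4, _SHEET_GAP))
    return layout


def _sidechain(resname: str, ca: np.ndarray, direction: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Extended side chain along ``direction`` (unit); returns (name, element, pos)."""
    d = direction / np.linalg.norm(direction)
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(d, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    cb = ca + 1.53 * d
    out = [("CB", "C", cb)]
    if resname == "ALA" or resname == "GLY":
        return out if resname == "ALA" else []
    cg = cb + 1.5 * d
    out.append(("CG", "C", cg))
    if resname == "LEU":
        out.append(("CD1", "C", cg + 1.5 * (0.8 * d + 0.6 * perp)))
        out.append(("CD2", "C", cg + 1.5 * (0.8 * d - 0.6 * perp)))
    elif resname == "GLU":
        cd = cg + 1.5 * d
        out.append(("CD", "C", cd))
        out.append(("OE1", "O", cd + 1.25 * (0.8 * d + 0.6 * perp)))
        out.append(("OE2", "O", cd + 1.25 * (0.8 * d - 0.6 * perp)))
    elif resname == "LYS":
        cd = cg + 1.5 * d
        ce = cd + 1.5 * d
        nz = ce + 1.5 * d
        out += [("CD", "C", cd), ("CE", "C", ce), ("NZ", "N", nz),
                ("HZ1", "H", nz + 1.0 * d)]
    return out


def build_toy_domain(n_strands: int, residues_per_strand: int, seed: int = 0,
                     chain: str = "A") -> Structure:
    """Idealized antiparallel beta-sandwich, poly-Ala with planted chemistry.

    Strands run alternately along +/-z with 4.8 Å sheet spacing and 3.4 Å
    Cα rise; carbonyls point across the sheet so the Kabsch-Sander criterion
    detects the ladders.  Three interface residues (outer face of the first
    sheet) are mutated to Lys, Glu and Leu (sites chosen by ``seed``) so all
    contact kinds can be planted.  Deterministic for a given seed.
    """
    if n_strands < 2:
        raise ValueError("a sheet needs at least 2 strands")
    if residues_per_strand < 3:
        raise ValueError("need at least 3 residues per strand")
    rng = np.random.default_rng(seed)
    layout = _strand_layout(n_strands)

    # choose mutation sites: central residues of distinct sheet-1 strands,
    # side chain pointing to the outer (-y) face
    n_sheet1 = sum(1 for _, y in layout if y == 0.0)
    candidate_strands = list(range(min(3, n_sheet1)))
    mut_resnames = ["LYS", "GLU", "LEU"]
    rng.shuffle(candidate_strands)
    mutations: dict[tuple[int, int], str] = {}
    for strand_s, resname in zip(candidate_strands, mut_resnames):
        k = residues_per_strand // 2
        if k % 2 == 0:
            k += 1  # odd spatial slot -> CB points to -y on sheet 1
        mutations[(strand_s, min(k, residues_per_strand - 1))] = resname

    atoms: list[Atom] = []
    serial = 1
    resseq = 0

    def add_atom(name, element, pos, resname):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element, chain=chain,
                          resseq=resseq, icode="", resname=resname, coords=np.asarray(pos)))
        serial += 1

    prev_end_ca = None
    for s, (x0, y0) in enumerate(layout):
        direction = 1 if s % 2 == 0 else -1
        # loop from the previous strand
        start_k = 0 if direction == 1 else residues_per_strand - 1
        start_ca = np.array([x0, y0, start_k * _CA_RISE])
        if prev_end_ca is not None:
            for t in range(1, _LOOP_LEN + 1):
                resseq += 1
                frac = t / (_LOOP_LEN + 1)
                base = prev_end_ca + frac * (start_ca - prev_end_ca)
                bump = np.array([0.0, 0.0, 2.5 * (1 if s % 2 == 1 else -1)])
                ca = base + bump
                add_atom("N", "N", ca + [0.0, 0.6, -1.1], "GLY")
                add_atom("CA", "C", ca, "GLY")
                add_atom("C", "C", ca + [0.0, 0.6, 1.1], "GLY")
                add_atom("O", "O", ca + [0.9, 1.2, 1.1], "GLY")
        for j in range(residues_per_strand):
            resseq += 1
            k = j if direction == 1 else residues_per_strand - 1 - j  # spatial slot
            z = k * _CA_RISE
            ca = np.array([x0, y0, z])
            side = 1.0 if (k + s) % 2 == 0 else -1.0       # carbonyl across sheet
            pleat = 1.0 if k % 2 == 0 else -1.0            # side chain up/down
            if y0 > 0:
                pleat = -pleat  # sheet 2 outer face is +y
            resname = mutations.get((s, k), "ALA") if y0 == 0.0 else "ALA"
            add_atom("N", "N", ca + [0.0, 0.0, -1.1 * direction], resname)
            # explicit amide hydrogen: completes the H-bond ladder geometry
            add_atom("H", "H", ca + [1.0 * side, 0.0, -1.1 * direction], resname)
            add_atom("CA", "C", ca, resname)
            add_atom("C", "C", ca + [0.0, 0.0, 1.1 * direction], resname)
            add_atom("O", "O", ca + [1.23 * side, 0.0, 1.1 * direction], resname)
            for name, element, pos in _sidechain(resname, ca, np.array([0.0, pleat, 0.0])):
                add_atom(name, element, pos, resname)
        end_k = residues_per_strand - 1 if direction == 1 else 0
        prev_end_ca = np.array([x0, y0, end_k * _CA_RISE])
    return Structure(atoms, name=f"toy{n_strands}x{residues_per_strand}")


def toy_element_map(structure: Structure, n_strands: int, residues_per_strand: int,
                    domain_label: str = "a") -> ElementMap:
    """Ground-truth element labels of a toy domain (by construction)."""
    chain = structure.atoms[0].chain
    labels: dict[tuple[str, int, str], str] = {}
    resseq = 0
    for s in range(n_strands):
        if s > 0:
            loop = STRAND_LABELS[s - 1] + STRAND_LABELS[s]
            for _ in range(_LOOP_LEN):
                resseq += 1
                labels[(chain, resseq, "")] = loop
        for _ in range(residues_per_strand):
            resseq += 1
            labels[(chain, resseq, "")] = STRAND_LABELS[s]
    return ElementMap(domain_label=domain_label, labels=labels)


def mutated_residues(structure: Structure) -> dict[str, tuple[str, int, str]]:
    """Residue ids of the planted Lys/Glu/Leu interface residues."""
    out: dict[str, tuple[str, int, str]] = {}
    for atom in structure.atoms:
        if atom.resname in ("LYS", "GLU", "LEU"):
            out[atom.resname] = atom.residue_id
    return out


# ---------------------------------------------------------------------------
# assembly at a requested orientation


def _heavy_center_axis(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(centre of mass, sign-fixed principal axis) over heavy atoms."""
    heavy = [a for a in structure.atoms if a.element.upper() != "H"]
    coords = np.array([a.coords for a in heavy])
    masses = np.array([a.mass for a in heavy])
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    cas = [a.coords for a in structure.atoms if a.name == "CA"]
    sign_ref = cas[-1] - cas[0]
    axis = inertia_principal_axis(coords, masses, sign_ref)
    return com, axis


def _place(structure: Structure, target_axis: np.ndarray, target_center: np.ndarray) -> Structure:
    com, axis = _heavy_center_axis(structure)
    rot = _rotation_between(axis, target_axis / np.linalg.norm(target_axis))
    placed = structure.copy()
    placed.set_coords((rot @ (structure.coords - com).T).T + target_center)
    return placed


def assemble_complex(
    dom_a: Structure,
    dom_b: Structure,
    torsion: float = 90.0,
    tilts: tuple[float, float] = (90.0, 90.0),
    d_c: float = 30.0,
) -> tuple[Structure, GroundTruth]:
    """Place domain b relative to domain a at the requested orientation.

    The orientation measures of the result (with a reference built from the
    result itself) equal the request: AC1/BC1 are the tilts, AB the torsion,
    dC the centre distance; AC2/BC2 are 90° by construction of the reference
    frame.  Any interdomain atom pair closer than 2 Å raises a clash error.
    """
    tilt_a, tilt_b = (float(t) for t in tilts)
    for t in (tilt_a, tilt_b):
        if t < 2.0 or t > 178.0:
            raise ValueError("tilts within 2° of the centre axis make the torsion ill-defined")
    ta, tb, ab = np.radians(tilt_a), np.radians(tilt_b), np.radians(torsion)
    x, y, z = np.eye(3)
    u_a = np.cos(ta) * x + np.sin(ta) * z
    u_b = np.cos(tb) * (-x) + np.sin(tb) * (np.cos(ab) * z - np.sin(ab) * y)

    placed_a = _place(dom_a, u_a, np.zeros(3))
    placed_b = _place(dom_b, u_b, np.array([d_c, 0.0, 0.0]))
    chain_b = "B" if placed_a.atoms[0].chain != "B" else "D"
    for atom in placed_b.atoms:
        atom.chain = chain_b

    from scipy.spatial import cKDTree  # local import to keep module load light
    dmin = cKDTree(placed_a.coords).query(placed_b.coords, k=1)[0].min()
    if dmin < 2.0:
        raise ValueError(f"unreachable geometry: interdomain clash at {dmin:.2f} Å")

    atoms = []
    for k, a in enumerate(placed_a.atoms + placed_b.atoms, start=1):
        a.serial = k
        atoms.append(a)
    complex_structure = Structure(atoms, name="synthetic-complex")

    def _sel(st: Structure, chain: str, label: str) -> DomainSelection:
        nums = [a.resseq for a in complex_structure.atoms if a.chain == chain]
        return DomainSelection(label=label, members=[(chain, (min(nums), max(nums)))])

    chain_a = placed_a.atoms[0].chain
    truth = GroundTruth(
        measures={"AB": float(torsion), "AC1": tilt_a, "AC2": 90.0,
                  "BC1": tilt_b, "BC2": 90.0, "dC": float(d_c)},
        selections={"a": _sel(complex_structure, chain_a, "a"),
                    "b": _sel(complex_structure, chain_b, "b")},
        element_maps={},
    )
    return complex_structure, truth


# ---------------------------------------------------------------------------
# trajectory synthesis


def _plant_indices(structure: Structure, rid_a: tuple, rid_b: tuple, kind: str):
    """Resolve mover side-chain atoms, mover tip and partner tip for a plant."""
    if kind not in _PLANT_GEOMETRY:
        raise ValueError(f"unknown contact kind {kind!r}")
    tip_a_name, tip_b_name, r_on, r_off = _PLANT_GEOMETRY[kind]
    res_a_atoms = structure.residue_atoms(rid_a)
    res_b_atoms = structure.residue_atoms(rid_b)
    names_a = {structure.atoms[i].name: i for i in res_a_atoms}
    names_b = {structure.atoms[i].name: i for i in res_b_atoms}
    if tip_a_name not in names_a:
        raise ValueError(f"plant {kind}: residue {rid_a} lacks atom {tip_a_name} "
                         f"(is it the right mutated residue type?)")
    if tip_b_name not in names_b:
        raise ValueError(f"plant {kind}: residue {rid_b} lacks atom {tip_b_name}")
    mover = [i for i in res_a_atoms if structure.atoms[i].name not in _BACKBONE]
    anchor = names_a["CA"]
    return mover, names_a[tip_a_name], names_b[tip_b_name], anchor, r_on, r_off


def synth_trajectory(complex_structure: Structure, spec: SynthSpec,
                     truth: GroundTruth | None = None) -> tuple[Trajectory, GroundTruth]:
    """Frame ensemble with Gaussian noise and planted contact lifetimes.

    Per frame, isotropic N(0, noise_sigma²) noise is added to every atom;
    each planted contact then either places the mover side chain so its tip
    atom sits at the contact distance from the partner tip (probability
    ``target_ratio``) or well beyond threshold+1 Å.  All Bernoulli draws are
    recorded in the ground truth.  Deterministic for a given spec.
    """
    if truth is None:
        truth = GroundTruth(measures={}, selections={}, element_maps={})
    planted = []
    seen_residues: set[tuple] = set()
    for rid_a, rid_b, kind, ratio in spec.planted_contacts:
        if rid_a in seen_residues:
            raise ValueError(f"residue {rid_a} appears in more than one plant; "
                             "its side chain cannot satisfy both")
        seen_residues.add(rid_a)
        planted.append((rid_a, rid_b, kind, float(ratio),
                        _plant_indices(complex_structure, rid_a, rid_b, kind)))

    rng = np.random.default_rng(spec.seed)
    base = complex_structure.coords
    n_atoms = base.shape[0]
    chain_atoms: dict[str, np.ndarray] = {}
    for k, atom in enumerate(complex_structure.atoms):
        chain_atoms.setdefault(atom.chain, []).append(k)
    chain_atoms = {c: np.asarray(v, dtype=int) for c, v in chain_atoms.items()}
    frames = np.empty((spec.n_frames, n_atoms, 3))
    presence = {(rid_a, rid_b, kind): np.zeros(spec.n_frames, dtype=bool)
                for rid_a, rid_b, kind, _, _ in planted}

    hz1_idx = {}
    for rid_a, rid_b, kind, _, (mover, tip_a, tip_b, anchor, _, _) in planted:
        if kind == "hbond":
            names = {complex_structure.atoms[i].name: i for i in mover}
            hz1_idx[(rid_a, rid_b, kind)] = names.get("HZ1")

    for f in range(spec.n_frames):
        coords = base + rng.normal(0.0, spec.noise_sigma, size=(n_atoms, 3)) \
            if spec.noise_sigma > 0 else base.copy()
        for rid_a, rid_b, kind, ratio, (mover, tip_a, tip_b, anchor, r_on, r_off) in planted:
            on = bool(rng.random() < ratio)
            presence[(rid_a, rid_b, kind)][f] = on
            r = r_on if on else r_off
            toward_a = coords[anchor] - coords[tip_b]
            toward_a /= np.linalg.norm(toward_a)
            perp = np.cross(toward_a, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(toward_a, [1.0, 0.0, 0.0])
            perp /= np.linalg.norm(perp)
            # re-pose the side chain extended from the tip back towards its
            # own backbone so trailing atoms leave the interface; among a few
            # deterministic directions pick the one clearest of the partner
            # domain (its other side chains also protrude into the gap)
            dists = np.linalg.norm(coords[mover] - coords[tip_a], axis=1)
            # the tip itself stays exactly on target; others fan out slightly
            spread = np.where(dists < 1e-9, 0.0, 0.15 * np.arange(len(mover)))
            partner_chain = chain_atoms[rid_b[0]]
            obstacle = coords[np.setdiff1d(partner_chain, [tip_b])]
            best = None
            for angle in (0.0, 12.0, -12.0, 24.0, -24.0, 36.0, -36.0):
                a_r = np.radians(angle)
                direction = np.cos(a_r) * toward_a + np.sin(a_r) * perp
                cand = (coords[tip_b] + r * direction
                        + np.outer(dists, direction) + np.outer(spread, perp))
                clearance = np.sqrt(
                    ((cand[:, None, :] - obstacle[None, :, :]) ** 2).sum(-1)).min()
                if best is None or clearance > best[0]:
                    best = (clearance, cand)
                if clearance > 2.0:
                    break
            coords[mover] = best[1]
            h = hz1_idx.get((rid_a, rid_b, kind))
            if on and h is not None:
                d = coords[tip_b] - coords[tip_a]
                coords[h] = coords[tip_a] + d / np.linalg.norm(d)
        frames[f] = coords

    truth.contact_presence = presence
    return Trajectory(topology=complex_structure, frames=frames), truth


def synthesize(spec: SynthSpec) -> tuple[Trajectory, GroundTruth]:
    """End-to-end synthetic system under the conditions of a SynthSpec.

    Builds two toy domains, assembles them at the requested orientation,
    plants the requested contacts (or, by default, one salt bridge at ratio
    0.65 between the Lys of domain a and the Glu of domain b) and emits the
    trajectory plus ground truth, including element maps for both domains.
    """
    dom_a = build_toy_domain(spec.strands_per_domain, spec.residues_per_strand,
                             seed=spec.seed, chain="A")
    dom_b = build_toy_domain(spec.strands_per_domain, spec.residues_per_strand,
                             seed=spec.seed + 1, chain="B")
    complex_structure, truth = assemble_complex(
        dom_a, dom_b, torsion=spec.torsion_ab, tilts=spec.tilts, d_c=spec.d_c)
    truth.element_maps = {
        "a": toy_element_map(dom_a, spec.strands_per_domain, spec.residues_per_strand, "a"),
        "b": ElementMap(domain_label="b", labels={
            ("B" if k[0] == "B" else k[0], k[1], k[2]): v
            for k, v in toy_element_map(
                dom_b, spec.strands_per_domain, spec.residues_per_strand, "b"
            ).labels.items()
        }),
    }
    spec_used = spec
    if not spec.planted_contacts:
        muts_a = mutated_residues_by_chain(complex_structure, truth.selections["a"])
        muts_b = mutated_residues_by_chain(complex_structure, truth.selections["b"])
        plants = [(muts_a["LYS"], muts_b["GLU"], "saltbridge", 0.65)]
        spec_used = SynthSpec(**{**spec.__dict__, "planted_contacts": plants})
    return synth_trajectory(complex_structure, spec_used, truth)


def mutated_residues_by_chain(structure: Structure, sel: DomainSelection) -> dict[str, tuple]:
    """Planted Lys/Glu/Leu residue ids within one domain selection."""
    out: dict[str, tuple] = {}
    for atom in structure.atoms:
        if atom.resname in ("LYS", "GLU", "LEU") and sel.contains(atom.chain, atom.resseq):
            out[atom.resname] = atom.residue_id
    return out
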