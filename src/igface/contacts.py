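"""Interdomain contact detection, typed by interaction chemistry.

Contacts between the two domains of a pair are detected per frame and
classified as hydrogen bond, salt bridge, hydrophobic or van der Waals from
geometric predicates over typed atoms (GetContacts-style defaults, all
config-exposed).  A residue pair's occurrence ratio is the fraction of frames
in which at least one contact of the kind joins the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, Trajectory

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "ChemRoles",
    "assign_chem_roles",
    "detect_contacts_frame",
    "contacts_over_trajectory",
    "contact_ratio",
    "residue_pair_keys",
    "write_contact_table",
    "read_contact_table",
]

KINDS = ("saltbridge", "hbond", "hydrophobic", "vdw")
#: more specific kinds win when one atom pair satisfies several predicates
KIND_PRECEDENCE = {"saltbridge": 0, "hbond": 1, "hydrophobic": 2, "vdw": 3}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "GLH", "ASH", "LYN",  # common MD variants
}

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "LYN": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"}, "HID": {"ND1"}, "HIE": {"NE2"}, "HIP": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "HID": {"NE2"}, "HIE": {"ND1"},
    "ASH": {"OD1", "OD2"}, "GLH": {"OE1", "OE2"},
}
_CATIONS = {
    "LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"}, "HIP": {"ND1", "NE2"},
}
_ANIONS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

# side-chain carbons covalently bonded to N or O (not apolar); the backbone
# C and CA are excluded for every residue
_POLAR_ADJACENT_C = {
    "SER": {"CB"}, "THR": {"CB"}, "ASP": {"CG"}, "GLU": {"CD"},
    "ASN": {"CG"}, "GLN": {"CD"}, "ARG": {"CD", "CZ"}, "LYS": {"CE"},
    "LYN": {"CE"}, "HIS": {"CG", "CD2", "CE1"}, "HID": {"CG", "CD2", "CE1"},
    "HIE": {"CG", "CD2", "CE1"}, "HIP": {"CG", "CD2", "CE1"},
    "TRP": {"CD1", "CE2"}, "TYR": {"CZ"}, "PRO": {"CD"},
    "ASH": {"CG"}, "GLH": {"CD"},
}

_VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HN", "HA"}


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds for the four contact channels.

    Defaults follow the commonly used GetContacts criteria: donor-acceptor
    3.5 Å with a 110° D-H...A angle for hydrogen bonds, 4.0 Å cation-anion
    for salt bridges, 4.5 Å between apolar carbons for hydrophobic contacts
    and vdW-radius sum + 0.5 Å for generic van der Waals contacts.
    ``heavy_atom_fallback`` accepts hydrogen bonds on the donor-acceptor
    distance alone (and widens the donor set to all polar N/O) for structures
    without hydrogens, the usual situation for X-ray inputs.
    """

    hbond_da_max: float = 3.5
    hbond_angle_min: float = 110.0
    saltbridge_max: float = 4.0
    hydrophobic_max: float = 4.5
    vdw_slack: float = 0.5
    heavy_atom_fallback: bool = True

    def __post_init__(self) -> None:
        for name in ("hbond_da_max", "saltbridge_max", "hydrophobic_max", "vdw_slack"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.hbond_angle_min <= 180.0:
            raise ValueError("hbond_angle_min must be in [0, 180] degrees")


@dataclass(frozen=True)
class ContactRecord:
    """One detected interdomain contact (a-domain atom first)."""

    frame: int
    kind: str
    atom_a: int
    atom_b: int
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    subtype: str = ""  # hbond only: ss / sb / bb (sidechain/backbone partners)


@dataclass
class ChemRoles:
    """Per-atom chemical roles backing the contact predicates."""

    donor: np.ndarray        # heavy atoms that can donate an H-bond
    acceptor: np.ndarray
    cation: np.ndarray
    anion: np.ndarray
    apolar: np.ndarray       # carbons with no bonded N/O
    polar_no: np.ndarray     # any N/O (fallback donor set)
    heavy: np.ndarray
    backbone: np.ndarray
    vdw_radius: np.ndarray
    donor_h: dict[int, list[int]]  # donor heavy atom -> bonded hydrogens


def assign_chem_roles(structure: Structure) -> ChemRoles:
    """Assign donor/acceptor/cation/anion/apolar roles from packaged tables.

    Nonstandard residues get a vdW radius only (with one summary warning).
    Bonded hydrogens are found geometrically (same residue, within 1.25 Å of
    the heavy atom).
    """
    n = len(structure)
    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    cation = np.zeros(n, dtype=bool)
    anion = np.zeros(n, dtype=bool)
    apolar = np.zeros(n, dtype=bool)
    polar_no = np.zeros(n, dtype=bool)
    heavy = np.zeros(n, dtype=bool)
    backbone = np.zeros(n, dtype=bool)
    radius = np.full(n, 1.70)
    nonstandard: set[str] = set()

    for i, atom in enumerate(structure.atoms):
        el = atom.element.upper()
        radius[i] = _VDW_RADII.get(el, 1.70)
        heavy[i] = el != "H"
        backbone[i] = atom.name in _BACKBONE_NAMES
        resn = atom.resname
        if resn not in _STANDARD_AA:
            nonstandard.add(resn)
            continue
        if el in ("N", "O"):
            polar_no[i] = True
        name = atom.name
        if name == "N" and resn != "PRO":
            donor[i] = True
        if name in ("O", "OXT"):
            acceptor[i] = True
        if name == "OXT":
            anion[i] = True
        if name in _SIDECHAIN_DONORS.get(resn, ()):
            donor[i] = True
        if name in _SIDECHAIN_ACCEPTORS.get(resn, ()):
            acceptor[i] = True
        if name in _CATIONS.get(resn, ()):
            cation[i] = True
        if name in _ANIONS.get(resn, ()):
            anion[i] = True
        if el == "C" and name not in ("C", "CA") and name not in _POLAR_ADJACENT_C.get(resn, ()):
            apolar[i] = True
    if nonstandard:
        warnings.warn(
            f"nonstandard residue(s) {sorted(nonstandard)}: vdW radius only",
            stacklevel=2,
        )

    # hydrogens bonded to donors, by geometry in the topology coordinates
    coords = structure.coords
    donor_h: dict[int, list[int]] = {}
    h_idx = np.flatnonzero(~heavy)
    if h_idx.size:
        tree = cKDTree(coords[h_idx])
        for i in np.flatnonzero(donor | polar_no):
            rid = structure.atoms[i].residue_id
            near = tree.query_ball_point(coords[i], 1.25)
            bonded = [int(h_idx[k]) for k in near
                      if structure.atoms[h_idx[k]].residue_id == rid]
            if bonded:
                donor_h[i] = bonded
    return ChemRoles(donor, acceptor, cation, anion, apolar, polar_no,
                     heavy, backbone, radius, donor_h)


def _hbond_geometry_ok(coords: np.ndarray, d_idx: int, a_idx: int,
                       roles: ChemRoles, criteria: ContactCriteria) -> bool:
    """Angle test for a donor->acceptor pair already within distance."""
    hydrogens = roles.donor_h.get(d_idx, [])
    if hydrogens:
        cos_min = np.cos(np.radians(criteria.hbond_angle_min))
        a = coords[a_idx]
        for h_idx in hydrogens:
            h = coords[h_idx]
            u = coords[d_idx] - h
            v = a - h
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0 or nv == 0:
                continue
            # D-H...A angle >= threshold  <=>  cos(angle at H) <= cos(threshold)
            if np.dot(u, v) / (nu * nv) <= cos_min:
                return True
        return False
    return criteria.heavy_atom_fallback


def _hbond_subtype(roles: ChemRoles, i: int, j: int) -> str:
    si = "b" if roles.backbone[i] else "s"
    sj = "b" if roles.backbone[j] else "s"
    return "".join(sorted((si, sj), reverse=True))  # ss, sb, bb


def detect_contacts_frame(
    coords: np.ndarray,
    roles: ChemRoles,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    criteria: ContactCriteria | None = None,
    structure: Structure | None = None,
    frame: int = 0,
) -> list[ContactRecord]:
    """Typed interdomain contacts in one frame.

    Every (a-atom, b-atom) pair is reported at most once, under its most
    specific satisfied kind (saltbridge > hbond > hydrophobic > vdw).
    ``structure`` supplies residue identifiers; required for record output.
    """
    criteria = criteria or ContactCriteria()
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("domain selections overlap")
    if structure is None:
        raise ValueError("structure is required to label residues")

    r_vdw_max = 2 * float(roles.vdw_radius.max()) + criteria.vdw_slack
    r_max = max(criteria.hbond_da_max, criteria.saltbridge_max,
                criteria.hydrophobic_max, r_vdw_max)
    tree_a = cKDTree(coords[sel_a])
    tree_b = cKDTree(coords[sel_b])
    pairs = tree_a.query_ball_tree(tree_b, r_max)

    records: list[ContactRecord] = []
    for ia_local, blist in enumerate(pairs):
        i = int(sel_a[ia_local])
        for ib_local in blist:
            j = int(sel_b[ib_local])
            d = float(np.linalg.norm(coords[i] - coords[j]))
            kind = None
            subtype = ""
            if d <= criteria.saltbridge_max and (
                (roles.cation[i] and roles.anion[j]) or (roles.anion[i] and roles.cation[j])
            ):
                kind = "saltbridge"
            elif d <= criteria.hbond_da_max:
                donor_i = roles.donor[i] or (criteria.heavy_atom_fallback and roles.polar_no[i])
                donor_j = roles.donor[j] or (criteria.heavy_atom_fallback and roles.polar_no[j])
                if donor_i and roles.acceptor[j] and _hbond_geometry_ok(coords, i, j, roles, criteria):
                    kind = "hbond"
                elif donor_j and roles.acceptor[i] and _hbond_geometry_ok(coords, j, i, roles, criteria):
                    kind = "hbond"
                if kind == "hbond":
                    subtype = _hbond_subtype(roles, i, j)
            if kind is None and d <= criteria.hydrophobic_max and roles.apolar[i] and roles.apolar[j]:
                kind = "hydrophobic"
            if kind is None and roles.heavy[i] and roles.heavy[j] and d <= (
                roles.vdw_radius[i] + roles.vdw_radius[j] + criteria.vdw_slack
            ):
                kind = "vdw"
            if kind is not None:
                records.append(ContactRecord(
                    frame=frame, kind=kind, atom_a=i, atom_b=j,
                    residue_a=structure.atoms[i].residue_id,
                    residue_b=structure.atoms[j].residue_id,
                    subtype=subtype,
                ))
    records.sort(key=lambda r: (r.frame, KIND_PRECEDENCE[r.kind],
                                structure.atoms[r.atom_a].serial,
                                structure.atoms[r.atom_b].serial))
    return records


def contacts_over_trajectory(
    traj: Trajectory,
    roles: ChemRoles,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    criteria: ContactCriteria | None = None,
) -> list[ContactRecord]:
    """Time-resolved contact table: per-frame detections, deterministically
    ordered by (frame, kind, atom serials)."""
    if criteria is None:
        # MD-style frames normally carry hydrogens: be strict by default
        criteria = ContactCriteria(heavy_atom_fallback=False)
        if not roles.donor_h:
            criteria = replace(criteria, heavy_atom_fallback=True)
    out: list[ContactRecord] = []
    for k in range(traj.frame_count):
        out.extend(detect_contacts_frame(
            traj.frames[k], roles, sel_a, sel_b, criteria,
            structure=traj.topology, frame=k,
        ))
    return out


def residue_pair_keys(records: Iterable[ContactRecord],
                      kind: str | None = None) -> set[tuple]:
    """Distinct (residue_a, residue_b) pairs, optionally for one kind."""
    return {(r.residue_a, r.residue_b) for r in records
            if kind is None or r.kind == kind}


def contact_ratio(records: Iterable[ContactRecord],
                  pair: tuple,
                  frame_count: int,
                  kind: str | None = None) -> float:
    """Occurrence ratio of a residue pair: fraction of frames with >=1
    matching record (multiple atom pairs in one frame count once)."""
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    ra, rb = pair
    frames = {r.frame for r in records
              if r.residue_a == ra and r.residue_b == rb
              and (kind is None or r.kind == kind)}
    return len(frames) / frame_count


# ---------------------------------------------------------------------------
# table I/O (tab-separated, GetContacts-compatible column order)


def _atom_ref(structure: Structure, idx: int) -> str:
    a = structure.atoms[idx]
    return f"{a.chain}:{a.resseq}{a.icode}:{a.name}"


def write_contact_table(records: Sequence[ContactRecord], structure: Structure,
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\tkind\tatom_a\tatom_b\tsubtype\n")
        for r in records:
            fh.write(f"{r.frame}\t{r.kind}\t{_atom_ref(structure, r.atom_a)}\t"
                     f"{_atom_ref(structure, r.atom_b)}\t{r.subtype or '-'}\n")


def _parse_ref(ref: str) -> tuple[tuple[str, int, str], str]:
    chain, res, name = ref.split(":")
    icode = ""
    while res and not res[-1].isdigit():
        icode = res[-1] + icode
        res = res[:-1]
    return (chain, int(res), icode), name


def read_contact_table(path: str | Path) -> list[ContactRecord]:
    """Re-read a contact table; atom indices are not recoverable from text
    and are stored as -1 (residue-level analyses are unaffected)."""
    records: list[ContactRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("frame"):
            raise ValueError(f"{path}: missing contact-table header")
        for line in fh:
            frame_s, kind, ref_a, ref_b, subtype = line.rstrip("\n").split("\t")
            rid_a, _ = _parse_ref(ref_a)
            rid_b, _ = _parse_ref(ref_b)
            records.append(ContactRecord(
                frame=int(frame_s), kind=kind, atom_a=-1, atom_b=-1,
                residue_a=rid_a, residue_b=rid_b,
                subtype="" if subtype == "-" else subtype,
            ))
    return records
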