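"""Structure, trajectory and charge I/O for paired-domain analyses.

Molecular structures are held in a lightweight, numpy-backed container that
preserves author residue numbering end to end (the EU-numbered residues of
antibody constant domains, e.g. Y407 or K439, are author numbers in the PDB
entries this package targets; nothing is ever renumbered).  Multi-model PDB
files double as the trajectory format: each MODEL block is one frame over a
shared topology.

Reading goes through :mod:`gemmi`; writing uses a fixed-width PDB writer so
that the B-factor column can be controlled exactly (open-book scores are
exported through it) and parse->write->parse is an identity to 3 decimals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "DomainSelection",
    "PDBParseError",
    "read_pdb",
    "read_trajectory",
    "read_pqr",
    "select_domain",
    "write_pdb",
    "write_trajectory",
    "write_bfactor_pdb",
]

#: fallback atomic masses for elements common in proteins (u)
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}


class PDBParseError(ValueError):
    """Malformed fixed-width PDB record; message carries the line number."""


@dataclass
class Atom:
    """One atom with author numbering preserved.

    ``resseq``/``icode`` follow the author numbering of the source file;
    ``charge`` is in elementary charges and stays ``None`` until a PQR file
    (or a synthetic charge table) supplies it.
    """

    serial: int
    name: str
    element: str
    chain: str
    resseq: int
    icode: str
    resname: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    charge: float | None = None
    mass: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")
        if self.mass == 0.0:
            self.mass = _MASSES.get(self.element.upper(), 12.011)

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)


class Structure:
    """Ordered atom collection with a (chain, resseq, icode) residue index."""

    def __init__(self, atoms: Sequence[Atom], name: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.name = name
        self._index: dict[tuple[str, int, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._index.setdefault(atom.residue_id, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (Å), a fresh copy."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected {(len(self.atoms), 3)} coordinates, got {coords.shape}")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Residue identifiers in first-appearance order."""
        return list(self._index)

    def residue_atoms(self, residue_id: tuple[str, int, str]) -> list[int]:
        return self._index[residue_id]

    def has_residue(self, residue_id: tuple[str, int, str]) -> bool:
        return residue_id in self._index

    def atom_index(self, chain: str, resseq: int, name: str, icode: str = "") -> int:
        """Index of a named atom; raises KeyError when absent."""
        for i in self._index.get((chain, resseq, icode), []):
            if self.atoms[i].name == name:
                return i
        raise KeyError(f"atom {chain}:{resseq}{icode}:{name} not found")

    def copy(self) -> "Structure":
        return Structure(
            [Atom(a.serial, a.name, a.element, a.chain, a.resseq, a.icode,
                  a.resname, a.coords.copy(), a.occupancy, a.bfactor,
                  a.charge, a.mass, a.het) for a in self.atoms],
            name=self.name,
        )


@dataclass
class Trajectory:
    """Frame ensemble over a fixed topology (multi-model PDB stands in for MD)."""

    topology: Structure
    frames: np.ndarray  # F x N x 3, Å

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be F x N x 3")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {len(self.topology)}"
            )

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class DomainSelection:
    """Named domain ("a" or "b"): chains with inclusive residue ranges.

    The two domains of a pair are labelled following the convention that the
    CL domain / CH3 domain A is "a" and the CH1 domain / CH3 domain B is "b".
    """

    label: str
    members: list[tuple[str, tuple[int, int]]]

    def __post_init__(self) -> None:
        if self.label not in ("a", "b"):
            raise ValueError(f"domain label must be 'a' or 'b', got {self.label!r}")
        if not self.members:
            raise ValueError("domain selection has no members")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chain, (lo, hi) in self.members:
            if hi < lo:
                raise ValueError(f"empty residue range {lo}-{hi} on chain {chain}")
            for plo, phi in seen.get(chain, []):
                if lo <= phi and plo <= hi:
                    raise ValueError(f"overlapping ranges on chain {chain}")
            seen.setdefault(chain, []).append((lo, hi))

    def contains(self, chain: str, resseq: int) -> bool:
        return any(c == chain and lo <= resseq <= hi for c, (lo, hi) in self.members)


# ---------------------------------------------------------------------------
# reading

def _prevalidate_pdb(path: Path) -> None:
    """Cheap fixed-width sanity scan so parse errors can name a line number."""
    n_atom_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                n_atom_records += 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: truncated {rec} record")
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise PDBParseError(
                            f"line {lineno}: malformed {what} coordinate {fieldtxt!r}"
                        ) from None
    if n_atom_records == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")


def _element_from_name(name: str) -> str:
    """Infer the element when columns 77-78 are blank: standard PDB layout
    puts the element in the first character(s) of the 4-char atom-name field."""
    stripped = name.strip()
    if not stripped:
        return "C"
    if stripped[0].isdigit():  # e.g. 1HG1
        stripped = stripped.lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _model_to_atoms(model: gemmi.Model, altloc_policy: str) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            # resolve altlocs: group by atom name
            groups: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                groups.setdefault(at.name, []).append(at)
            for name, group in groups.items():
                if len(group) == 1 or altloc_policy == "all":
                    chosen = group
                elif altloc_policy == "first":
                    chosen = [min(group, key=lambda a: a.altloc or "~")]
                else:  # highest occupancy, ties -> lexicographically first altloc
                    chosen = [max(group, key=lambda a: (a.occ, -ord(a.altloc or "~")))]
                for at in chosen:
                    element = at.element.name if at.element and at.element.name != "X" else ""
                    if not element:
                        element = _element_from_name(name)
                    atoms.append(Atom(
                        serial=at.serial,
                        name=name,
                        element=element,
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        resname=res.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        bfactor=at.b_iso,
                        het=(res.het_flag == "H"),
                    ))
    return atoms


def read_pdb(path: str | Path, altloc_policy: str = "highest_occupancy") -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only).

    ``altloc_policy``: ``highest_occupancy`` (default; ties break to the
    lexicographically first altloc id), ``first``, or ``all``.
    Multi-model files are accepted with a logged notice; use
    :func:`read_trajectory` to keep every model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    if len(st) > 1:
        logger.info("%s: %d models present; keeping model 1 (use read_trajectory for all)",
                    path.name, len(st))
    atoms = _model_to_atoms(st[0], altloc_policy)
    if not atoms:
        raise PDBParseError(f"{path}: no atoms parsed")
    return Structure(atoms, name=path.stem)


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB as a trajectory: topology from model 1, one
    frame per MODEL block, ordered by MODEL number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    models = sorted(st, key=lambda m: m.num)
    topo_atoms = _model_to_atoms(models[0], altloc_policy="highest_occupancy")
    topology = Structure(topo_atoms, name=path.stem)
    n = len(topology)
    frames = np.empty((len(models), n, 3), dtype=float)
    for k, model in enumerate(models):
        atoms = _model_to_atoms(model, altloc_policy="highest_occupancy")
        if len(atoms) != n:
            raise ValueError(
                f"{path}: model {model.num} has {len(atoms)} atoms, "
                f"model {models[0].num} has {n}"
            )
        frames[k] = [a.coords for a in atoms]
    return Trajectory(topology=topology, frames=frames)


def read_pqr(path: str | Path) -> dict[tuple[str, int, str], tuple[float, float]]:
    """Read a whitespace-delimited PQR file.

    Returns ``(chain, resseq, atom_name) -> (charge_e, radius_Å)``.  PQR files
    written without a chain column get chain ``""``; match them against
    single-chain structures with :func:`attach_charges`.
    """
    path = Path(path)
    table: dict[tuple[str, int, str], tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            parts = line.split()
            # ATOM serial name resname [chain] resseq x y z charge radius
            if len(parts) == 11:
                _, _, name, _resn, chain, resseq_s = parts[:6]
                rest = parts[6:]
            elif len(parts) == 10:
                _, _, name, _resn, resseq_s = parts[:5]
                chain = ""
                rest = parts[5:]
            else:
                raise PDBParseError(f"line {lineno}: unrecognized PQR record with {len(parts)} fields")
            try:
                resseq = int(resseq_s)
                charge = float(rest[3])
                radius = float(rest[4])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: non-numeric PQR field ({exc})") from None
            table[(chain, resseq, name)] = (charge, radius)
    if not table:
        raise PDBParseError(f"{path}: no PQR atom records")
    return table


def attach_charges(structure: Structure,
                   table: Mapping[tuple[str, int, str], tuple[float, float]]) -> int:
    """Set ``Atom.charge`` from a PQR table, matching (chain, resseq, name).

    Extra PQR atoms absent from the structure are ignored with a warning that
    reports the count; returns the number of atoms that received a charge.
    """
    matched_keys = set()
    n_set = 0
    chains = {a.chain for a in structure.atoms}
    chainless_ok = len(chains) == 1
    for atom in structure.atoms:
        key = (atom.chain, atom.resseq, atom.name)
        if key not in table and chainless_ok:
            key = ("", atom.resseq, atom.name)
        if key in table:
            atom.charge = table[key][0]
            matched_keys.add(key)
            n_set += 1
    extra = len(table) - len(matched_keys)
    if extra:
        warnings.warn(f"{extra} PQR atom(s) had no match in the structure and were ignored",
                      stacklevel=2)
    return n_set


def select_domain(structure: Structure, sel: DomainSelection,
                  include_het: bool = False) -> np.ndarray:
    """Atom indices covered by the selection, in input order.

    Waters and HETATM records are excluded unless ``include_het`` (protein to
    protein interfaces only); every referenced residue range must match at
    least one residue or an error names the missing (chain, resseq).
    """
    hit_ranges = [False] * len(sel.members)
    idx: list[int] = []
    for i, atom in enumerate(structure.atoms):
        if atom.resname in _WATER_RESNAMES:
            continue
        if atom.het and not include_het:
            continue
        for j, (chain, (lo, hi)) in enumerate(sel.members):
            if atom.chain == chain and lo <= atom.resseq <= hi:
                idx.append(i)
                hit_ranges[j] = True
                break
    for j, hit in enumerate(hit_ranges):
        if not hit:
            chain, (lo, hi) = sel.members[j]
            raise KeyError(f"selection {sel.label}: no residues found for {chain}:{lo}-{hi}")
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# writing

def _format_atom_line(atom: Atom, coords: np.ndarray, bfactor: float | None = None) -> str:
    record = "HETATM" if atom.het else "ATOM"
    name = atom.name
    # standard alignment rule: 1/2-char element names start in column 14
    if len(name) < 4:
        name = (" " + name) if len(atom.element) == 1 else name
    b = atom.bfactor if bfactor is None else bfactor
    if not (-99.99 <= b <= 999.99):
        warnings.warn(f"B-factor {b:.3g} not representable in %6.2f; clipped", stacklevel=3)
        b = min(max(b, -99.99), 999.99)
    return (
        f"{record:<6}{atom.serial % 100000:>5} {name:<4} {atom.resname:<3} "
        f"{atom.chain[:1]:>1}{atom.resseq:>4}{atom.icode or ' ':1}   "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{atom.occupancy:6.2f}{b:6.2f}          {atom.element.upper():>2}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB with fixed-width ATOM/HETATM records."""
    with open(path, "w") as fh:
        for atom in structure.atoms:
            fh.write(_format_atom_line(atom, atom.coords) + "\n")
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    with open(path, "w") as fh:
        for k in range(traj.frame_count):
            fh.write(f"MODEL     {k + 1:>4}\n")
            for atom, xyz in zip(traj.topology.atoms, traj.frames[k]):
                fh.write(_format_atom_line(atom, xyz) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_bfactor_pdb(structure: Structure,
                      scores: Mapping[tuple[str, int, str], float] | Mapping[tuple[str, int], float],
                      path: str | Path) -> None:
    """Write the structure with the B-factor column replaced by per-residue
    scores (open-book contact counts); residues without a score get 0.00.

    Score keys may be (chain, resseq, icode) or (chain, resseq).
    """
    norm: dict[tuple[str, int, str], float] = {}
    for key, val in scores.items():
        if len(key) == 2:
            key = (key[0], key[1], "")
        norm[tuple(key)] = float(val)
    for key in norm:
        if not structure.has_residue(key):
            raise KeyError(f"score refers to residue {key} absent from structure")
    with open(path, "w") as fh:
        for atom in structure.atoms:
            b = norm.get(atom.residue_id, 0.0)
            fh.write(_format_atom_line(atom, atom.coords, bfactor=b) + "\n")
        fh.write("END\n")
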