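"""Interdomain electrostatic interaction energies (LIE-style).

Per-frame Coulomb sums between two atom selections,

    E = k * sum_{i in a, j in b, r_ij <= cutoff} q_i q_j / (eps * r_ij),

with k = 332.0636 kcal·Å/(mol·e²).  No solvent screening, no vdW term and no
periodic imaging: these are bare pairwise electrostatics of whole molecules,
reported per frame with trajectory mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Structure, Trajectory

__all__ = ["COULOMB_K", "EnergySeries", "coulomb_energy_frame", "energy_series",
           "write_energy_series", "residue_charge_table"]

COULOMB_K = 332.0636  # kcal·Å/(mol·e²)

#: coarse residue-level formal charges for charge-only workflows: the full
#: negative charge split over the carboxylate oxygens, the positive charge on
#: the terminal amine/guanidinium nitrogens
_FORMAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}


@dataclass
class EnergySeries:
    """Per-frame electrostatic energies with summary statistics (kcal/mol)."""

    energies: np.ndarray
    mean: float
    sd: float

    def __len__(self) -> int:
        return len(self.energies)


def residue_charge_table(structure: Structure) -> np.ndarray:
    """Per-atom charges from the packaged coarse formal-charge table
    (Asp/Glu -1 over the carboxylate oxygens, Lys/Arg +1); all other atoms 0.
    A stand-in when no PQR charges are available."""
    return np.array([
        _FORMAL_CHARGES.get((a.resname, a.name), 0.0) for a in structure.atoms
    ])


def _charges_for(structure: Structure, sel: np.ndarray) -> np.ndarray:
    out = np.empty(len(sel))
    for k, i in enumerate(sel):
        q = structure.atoms[i].charge
        if q is None:
            a = structure.atoms[i]
            raise ValueError(
                f"atom {a.chain}:{a.resseq}:{a.name} has no charge; "
                "load a PQR file or use residue_charge_table"
            )
        out[k] = q
    return out


def coulomb_energy_frame(
    coords: np.ndarray,
    charges: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    cutoff: float | None = 12.0,
    dielectric: float = 1.0,
) -> float:
    """Interdomain Coulomb energy of one frame (kcal/mol).

    ``charges`` is a per-atom array over the full topology (e); pairs beyond
    ``cutoff`` (Å; ``None`` disables it) are excluded.  Any interdomain pair
    closer than 0.5 Å indicates clashing or corrupt coordinates and raises.
    """
    if cutoff is not None and cutoff <= 0:
        raise ValueError("cutoff must be positive (or None)")
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    coords = np.asarray(coords, dtype=float)
    r = cdist(coords[sel_a], coords[sel_b])
    if (r < 0.5).any():
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ValueError(
            f"interdomain atom pair at {r[i, j]:.3f} Å (< 0.5 Å): clash or corrupt input"
        )
    qq = np.outer(np.asarray(charges)[sel_a], np.asarray(charges)[sel_b])
    with np.errstate(divide="ignore"):
        terms = qq / r
    if cutoff is not None:
        terms = np.where(r <= cutoff, terms, 0.0)
    return float(COULOMB_K * terms.sum() / dielectric)


def energy_series(
    traj: Trajectory,
    charges: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    cutoff: float | None = 12.0,
    dielectric: float = 1.0,
) -> EnergySeries:
    """Per-frame interdomain electrostatic energies with mean and sample sd."""
    energies = np.array([
        coulomb_energy_frame(traj.frames[k], charges, sel_a, sel_b, cutoff, dielectric)
        for k in range(traj.frame_count)
    ])
    sd = float(energies.std(ddof=1)) if len(energies) > 1 else 0.0
    return EnergySeries(energies=energies, mean=float(energies.mean()), sd=sd)


def write_energy_series(series: EnergySeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\tE_elec\n")
        for k, e in enumerate(series.energies):
            fh.write(f"{k}\t{e:.6f}\n")
        fh.write(f"# mean {series.mean:.6f} +/- {series.sd:.6f} kcal/mol\n")
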