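"""Interdomain orientation coordinates for paired Ig-like domains.

The relative orientation of two domains is described by six measures built
from a reference coordinate system:

* each domain's first principal axis of inertia (lowest eigenvalue of the
  inertia tensor about the centre of mass) is aligned to the world z axis;
* the centre axis connecting the two domain centres of mass is rotated, about
  z, as close as possible to the world x axis;
* the resulting per-domain reference coordinates are Kabsch-aligned onto any
  sample frame, and the rotations carry the unit vectors into the sample:
  A1/B1 (the z images) and A2/B2 (the y images).

The six measures are the four tilt angles of A1/A2 towards the centre axis C
and of B1/B2 towards -C (AC1, AC2, BC1, BC2), the centre-axis length dC, and
the torsion AB between the planes spanned by A1/C and B1/C, signed
right-handed about the a->b axis in (-180, 180].  For Fv domains the same
fields are conventionally called HL, LC1, LC2, HC1, HC2, dC, and for the
constant CH1-CL pair cHL, cLC1 etc.; :func:`alias_measures` renames them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .structio import DomainSelection, Structure, Trajectory, select_domain

__all__ = [
    "MEASURE_NAMES",
    "OrientationReference",
    "KDEDensity",
    "kabsch",
    "superpose_rmsd",
    "inertia_principal_axis",
    "build_reference",
    "measure_frame",
    "measure_trajectory",
    "alias_measures",
    "kde_density",
    "compute_rmsf",
]

MEASURE_NAMES = ("AB", "AC1", "AC2", "BC1", "BC2", "dC")

#: naming conventions per domain-pair kind
_ALIASES = {
    "fv": {"AB": "HL", "AC1": "LC1", "AC2": "LC2", "BC1": "HC1", "BC2": "HC2", "dC": "dC"},
    "ch1-cl": {"AB": "cHL", "AC1": "cLC1", "AC2": "cLC2", "BC1": "cHC1", "BC2": "cHC2", "dC": "dC"},
    "ch3-ch3": {m: m for m in MEASURE_NAMES},
}


# ---------------------------------------------------------------------------
# rigid-body building blocks


def kabsch(mobile: np.ndarray, target: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of paired point sets (proper rotation).

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile onto target;
    a reflection is never returned (determinant sign correction).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching N x 3 arrays")
    if mobile.shape[0] < 3:
        raise ValueError("at least 3 paired points required")
    if weights is None:
        weights = np.ones(mobile.shape[0])
    w = np.asarray(weights, dtype=float)[:, None] / np.sum(weights)
    cm = (w * mobile).sum(axis=0)
    ct = (w * target).sum(axis=0)
    p = mobile - cm
    q = target - ct
    h = (w * p).T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - rot @ cm
    diff = (rot @ mobile.T).T + t - target
    rmsd = float(np.sqrt((w[:, 0] * np.einsum("ij,ij->i", diff, diff)).sum()))
    return rot, t, rmsd


def superpose_rmsd(coords_mobile: np.ndarray, coords_target: np.ndarray,
                   pairing: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal superposition RMSD over an atom pairing.

    ``pairing`` is an (n, 2) index array (mobile index, target index);
    identity pairing when omitted.
    """
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        coords_mobile = np.asarray(coords_mobile)[pairing[:, 0]]
        coords_target = np.asarray(coords_target)[pairing[:, 1]]
    return kabsch(coords_mobile, coords_target)


def inertia_principal_axis(coords: np.ndarray, masses: np.ndarray,
                           sign_reference: np.ndarray | None = None) -> np.ndarray:
    """Unit eigenvector of the inertia tensor for the smallest eigenvalue.

    The +/- ambiguity is resolved so the dot product with ``sign_reference``
    (by convention the first -> last alignment-atom vector) is positive.
    A near-degenerate lowest pair (relative gap < 1e-6) raises.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = (masses[:, None, None]
               * (r2[:, None, None] * np.eye(3)[None, :, :]
                  - np.einsum("ij,ik->ijk", r, r))).sum(axis=0)
    evals, evecs = np.linalg.eigh(inertia)
    scale = max(abs(evals[-1]), 1e-300)
    if (evals[1] - evals[0]) / scale < 1e-6:
        raise ValueError(
            "degenerate inertia spectrum: the principal axis is ill-defined; "
            "use more (non-collinear) atoms"
        )
    axis = evecs[:, 0]
    if sign_reference is not None and np.dot(axis, sign_reference) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # a == -b: rotate 180 degrees about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_rotation(perp, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


# ---------------------------------------------------------------------------
# reference construction and measurement


@dataclass
class _DomainReference:
    align_idx: np.ndarray       # Cα atom indices (into the full structure)
    ref_coords: np.ndarray      # aligned Cα coordinates (world frame)
    center_idx: np.ndarray      # atoms defining the centre of mass
    center_weights: np.ndarray


@dataclass
class OrientationReference:
    """Per-domain reference coordinates aligned to the world frame.

    After construction each domain's principal axis is exactly +z and its
    centre axis lies in the x-z plane with positive x component.
    """

    domain_a: _DomainReference
    domain_b: _DomainReference
    center_mode: str = "heavy"


def _domain_arrays(structure: Structure, sel: DomainSelection, center_mode: str):
    idx = select_domain(structure, sel)
    atoms = structure.atoms
    ca_idx = np.array([i for i in idx if atoms[i].name == "CA"], dtype=int)
    if ca_idx.size < 3:
        raise ValueError(f"selection {sel.label}: fewer than 3 CA atoms")
    if center_mode == "ca":
        center_idx = ca_idx
    else:
        center_idx = np.array([i for i in idx if atoms[i].element.upper() != "H"], dtype=int)
    weights = np.array([atoms[i].mass for i in center_idx])
    return ca_idx, center_idx, weights


def build_reference(structure: Structure, sel_a: DomainSelection, sel_b: DomainSelection,
                    center_mode: str = "heavy") -> OrientationReference:
    """Create the reference coordinate system from a reference structure.

    ``center_mode`` picks the atoms defining centres of mass and inertia
    tensors: ``heavy`` (default, mass-weighted heavy atoms) or ``ca``.
    Kabsch alignment onto samples always uses the Cα atoms.
    """
    coords = structure.coords
    doms = {}
    arrays = {"a": _domain_arrays(structure, sel_a, center_mode),
              "b": _domain_arrays(structure, sel_b, center_mode)}
    centers = {}
    for label, (ca_idx, center_idx, weights) in arrays.items():
        centers[label] = (weights[:, None] * coords[center_idx]).sum(axis=0) / weights.sum()
    for label, (ca_idx, center_idx, weights) in arrays.items():
        other = "b" if label == "a" else "a"
        c_axis = centers[other] - centers[label]
        c_axis = c_axis / np.linalg.norm(c_axis)
        sign_ref = coords[ca_idx[-1]] - coords[ca_idx[0]]
        p_axis = inertia_principal_axis(coords[center_idx], weights, sign_ref)
        if np.degrees(np.arccos(np.clip(abs(np.dot(p_axis, c_axis)), -1, 1))) < 1.0:
            raise ValueError(
                f"domain {label}: centre axis within 1 degree of the principal axis; "
                "x alignment is undefined"
            )
        r1 = _rotation_between(p_axis, np.array([0.0, 0.0, 1.0]))
        c_rot = r1 @ c_axis
        phi = np.arctan2(c_rot[1], c_rot[0])
        rot = _axis_rotation(np.array([0.0, 0.0, 1.0]), -phi) @ r1
        ref_coords = (rot @ (coords[ca_idx] - centers[label]).T).T
        doms[label] = _DomainReference(
            align_idx=ca_idx, ref_coords=ref_coords,
            center_idx=center_idx, center_weights=weights,
        )
    return OrientationReference(domain_a=doms["a"], domain_b=doms["b"],
                                center_mode=center_mode)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _torsion_deg(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle from u to v about axis, right-handed, in (-180, 180]."""
    axis = axis / np.linalg.norm(axis)
    u_p = u - np.dot(u, axis) * axis
    v_p = v - np.dot(v, axis) * axis
    ang = np.degrees(np.arctan2(np.dot(np.cross(u_p, v_p), axis), np.dot(u_p, v_p)))
    return float(ang) if ang > -180.0 else 180.0


def measure_frame(coords: np.ndarray, reference: OrientationReference,
                  rmsd_warn: float = 5.0) -> dict[str, float]:
    """The six orientation measures of one sample frame.

    The per-domain references are Kabsch-aligned (Cα) onto the sample and the
    resulting rotations are applied to the world unit vectors, giving A1/A2
    and B1/B2; the centre axis comes from the sample's domain centres.
    """
    vecs = {}
    centers = {}
    for label, dom in (("a", reference.domain_a), ("b", reference.domain_b)):
        sample = np.asarray(coords)[dom.align_idx]
        rot, _, rmsd = kabsch(dom.ref_coords, sample)
        if rmsd > rmsd_warn:
            warnings.warn(
                f"domain {label}: Kabsch RMSD {rmsd:.2f} Å to the reference; "
                "the reference may not match this sample", stacklevel=2,
            )
        vecs[label] = (rot @ np.array([0.0, 0.0, 1.0]), rot @ np.array([0.0, 1.0, 0.0]))
        w = dom.center_weights
        centers[label] = (w[:, None] * np.asarray(coords)[dom.center_idx]).sum(axis=0) / w.sum()
    c_vec = centers["b"] - centers["a"]
    d_c = float(np.linalg.norm(c_vec))
    c_hat = c_vec / d_c
    a1, a2 = vecs["a"]
    b1, b2 = vecs["b"]
    return {
        "AB": _torsion_deg(a1, b1, c_hat),
        "AC1": _angle_deg(a1, c_hat),
        "AC2": _angle_deg(a2, c_hat),
        "BC1": _angle_deg(b1, -c_hat),
        "BC2": _angle_deg(b2, -c_hat),
        "dC": d_c,
    }


def measure_trajectory(traj: Trajectory, reference: OrientationReference) -> pd.DataFrame:
    """Per-frame orientation measures; one row per frame, order preserved."""
    rows = [measure_frame(traj.frames[k], reference) for k in range(traj.frame_count)]
    df = pd.DataFrame(rows, columns=list(MEASURE_NAMES))
    df.index.name = "frame"
    return df


def alias_measures(df: pd.DataFrame, domain_pair_kind: str) -> pd.DataFrame:
    """Rename measure columns to the convention of a domain-pair kind
    (``fv`` -> HL/LC1/..., ``ch1-cl`` -> cHL/cLC1/..., ``ch3-ch3`` -> as is)."""
    key = domain_pair_kind.lower()
    if key not in _ALIASES:
        raise ValueError(f"unknown domain pair kind {domain_pair_kind!r}; "
                         f"supported: {sorted(_ALIASES)}")
    return df.rename(columns=_ALIASES[key])


# ---------------------------------------------------------------------------
# distributions and fluctuations


@dataclass
class KDEDensity:
    """Gaussian KDE of an angle distribution on a regular grid."""

    grid: np.ndarray       # degrees, 0.1° steps
    density: np.ndarray    # probability density per degree
    bandwidth: float       # degrees

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde_density(samples: np.ndarray, bandwidth: float | None = None) -> KDEDensity:
    """Gaussian kernel density estimate of angle samples (degrees).

    The grid spans the samples ± 4 bandwidths in 0.1° steps; the default
    bandwidth is Silverman's rule.  Zero-variance samples need an explicit
    bandwidth to be meaningful and are rejected.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    std = samples.std(ddof=1)
    if std == 0:
        raise ValueError("samples have zero variance; supply an explicit bandwidth "
                         "and jitter, or report the single value directly")
    if bandwidth is None:
        kde = gaussian_kde(samples, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = gaussian_kde(samples, bw_method=bandwidth / std)
    bw = float(kde.factor * std)
    lo = samples.min() - 4 * bw
    hi = samples.max() + 4 * bw
    grid = np.arange(lo, hi + 0.1, 0.1)
    return KDEDensity(grid=grid, density=kde(grid), bandwidth=bw)


def compute_rmsf(traj: Trajectory, sel: DomainSelection,
                 reference_frame: int = 0) -> dict[tuple[str, int, str], float]:
    """Per-residue Cα root-mean-square fluctuation after superposition.

    Every frame is superposed (Cα, Kabsch) onto the chosen reference frame;
    RMSF(residue) is the RMS displacement of its Cα from the time-average
    position.  Residues without a Cα are skipped with a warning.
    """
    if traj.frame_count < 2:
        raise ValueError("RMSF needs at least 2 frames")
    topo = traj.topology
    idx = select_domain(topo, sel)
    ca_map: dict[tuple[str, int, str], int] = {}
    skipped = []
    residues_seen = []
    for i in idx:
        rid = topo.atoms[i].residue_id
        if rid not in residues_seen:
            residues_seen.append(rid)
        if topo.atoms[i].name == "CA":
            ca_map[rid] = i
    for rid in residues_seen:
        if rid not in ca_map:
            skipped.append(rid)
    if skipped:
        warnings.warn(f"{len(skipped)} residue(s) without CA skipped in RMSF", stacklevel=2)
    ca_idx = np.array(list(ca_map.values()), dtype=int)
    ref = traj.frames[reference_frame][ca_idx]
    aligned = np.empty((traj.frame_count, ca_idx.size, 3))
    for k in range(traj.frame_count):
        rot, t, _ = kabsch(traj.frames[k][ca_idx], ref)
        aligned[k] = (rot @ traj.frames[k][ca_idx].T).T + t
    mean_pos = aligned.mean(axis=0)
    sq = ((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0)
    rmsf = np.sqrt(sq)
    return {rid: float(rmsf[k]) for k, rid in enumerate(ca_map)}
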