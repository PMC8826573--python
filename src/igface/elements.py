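"""Coarse-graining of Ig domains into beta-strands A-G and connecting loops.

The immunoglobulin fold is a beta-sandwich; for constant domains a 3-stranded
sheet packs against a 4-stranded sheet (7 strands, labelled A-G along the
sequence), with loops named by their flanking strands (AB, BC, ... FG).
Contact maps are aggregated on these elements.

Two routes produce an :class:`ElementMap`:

* :func:`load_canonical_elements` reads a packaged per-domain-kind annotation
  (YAML: element label -> author residue-number ranges);
* :func:`assign_strands` detects strands from backbone hydrogen-bond ladders
  using the Kabsch-Sander electrostatic criterion, as a lightweight stand-in
  for a full secondary-structure assignment program.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .structio import DomainSelection, Structure, select_domain

__all__ = ["ElementMap", "STRAND_LABELS", "load_canonical_elements", "assign_strands",
           "load_element_file"]

STRAND_LABELS = ("A", "B", "C", "D", "E", "F", "G")
LOOP_LABELS = ("AB", "BC", "CD", "DE", "EF", "FG")
ALL_LABELS = STRAND_LABELS + LOOP_LABELS + ("Nterm", "Cterm")

_KIND_FILES = {
    "CH3": "ch3.yaml",
    "CH1": "ch1.yaml",
    "CL-kappa": "cl_kappa.yaml",
    "CL-lambda": "cl_lambda.yaml",
    "VH": "vh.yaml",
    "VL": "vl.yaml",
}

# Kabsch-Sander H-bond energy: E = q1*q2*f*(1/rON + 1/rCH - 1/rOH - 1/rCN),
# q1*q2*f = 0.42*0.20*332 = 27.888 kcal*Å/mol; bond when E < -0.5 kcal/mol.
_KS_PREFACTOR = 0.084 * 332.0
_KS_CUTOFF = -0.5


@dataclass
class ElementMap:
    """Residue -> structural-element label for one domain of a pair."""

    domain_label: str
    labels: dict[tuple[str, int, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, lab in self.labels.items():
            if lab not in ALL_LABELS:
                raise ValueError(f"unknown element label {lab!r} for residue {rid}")

    def label_of(self, residue_id: tuple[str, int, str]) -> str:
        return self.labels[residue_id]

    def __contains__(self, residue_id: tuple[str, int, str]) -> bool:
        return residue_id in self.labels

    def residues_of(self, label: str) -> list[tuple[str, int, str]]:
        return [rid for rid, lab in self.labels.items() if lab == label]


def _ranges_from_yaml(data: dict) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for label, ranges in data["elements"].items():
        out[str(label)] = [(int(lo), int(hi)) for lo, hi in ranges]
    return out


def load_element_file(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a user-supplied annotation file (element label -> residue ranges)."""
    with open(path) as fh:
        return _ranges_from_yaml(yaml.safe_load(fh))


def load_canonical_elements(
    domain_kind: str,
    residues: list[tuple[str, int, str]],
    domain_label: str = "a",
) -> ElementMap:
    """Element map for a known domain kind over the given residues.

    ``residues`` carries the author numbering of the actual structure; every
    residue is assigned exactly one label.  Residues before the A strand are
    ``Nterm``, after the G strand ``Cterm``; residues falling in an
    unannotated gap between elements inherit the preceding element's loop
    context (annotation files are written gap-free so this is a safety net).
    """
    if domain_kind not in _KIND_FILES:
        raise ValueError(
            f"unknown domain kind {domain_kind!r}; supported: {sorted(_KIND_FILES)}"
        )
    ref = importlib.resources.files("igface.data.elements") / _KIND_FILES[domain_kind]
    ranges = _ranges_from_yaml(yaml.safe_load(ref.read_text()))
    first = min(lo for spans in ranges.values() for lo, _ in spans)
    last = max(hi for spans in ranges.values() for _, hi in spans)
    labels: dict[tuple[str, int, str], str] = {}
    for rid in residues:
        _, resseq, _ = rid
        if resseq < first:
            labels[rid] = "Nterm"
            continue
        if resseq > last:
            labels[rid] = "Cterm"
            continue
        hit = None
        for label, spans in ranges.items():
            if any(lo <= resseq <= hi for lo, hi in spans):
                hit = label
                break
        if hit is None:
            # gap between annotated ranges: attach to nearest preceding range
            best = max(
                ((label, hi) for label, spans in ranges.items()
                 for _, hi in spans if hi < resseq),
                key=lambda t: t[1],
            )
            hit = best[0]
        labels[rid] = hit
    return ElementMap(domain_label=domain_label, labels=labels)


# ---------------------------------------------------------------------------
# strand detection from backbone hydrogen bonds


def _backbone_table(structure: Structure, indices: np.ndarray):
    """Per-residue backbone coordinates (N, CA, C, O) and amide-H estimate."""
    residues: list[tuple[str, int, str]] = []
    seen = set()
    for i in indices:
        rid = structure.atoms[i].residue_id
        if rid not in seen:
            seen.add(rid)
            residues.append(rid)
    coords = {}
    for rid in residues:
        names = {}
        for i in structure.residue_atoms(rid):
            a = structure.atoms[i]
            if a.name in ("N", "CA", "C", "O", "H", "HN"):
                names[a.name] = a.coords
        if not all(k in names for k in ("N", "CA", "C", "O")):
            raise ValueError(f"residue {rid}: backbone N/CA/C/O required for strand detection")
        coords[rid] = names
    # amide hydrogen: explicit if present, else 1 Å from N opposite the
    # previous residue's carbonyl oxygen (the standard planar-amide estimate)
    h_pos: dict[tuple[str, int, str], np.ndarray | None] = {}
    for k, rid in enumerate(residues):
        names = coords[rid]
        if "H" in names or "HN" in names:
            h_pos[rid] = names.get("H", names.get("HN"))
        elif k > 0 and residues[k - 1][0] == rid[0]:
            prev = coords[residues[k - 1]]
            d = prev["C"] - prev["O"]
            n = np.linalg.norm(d)
            h_pos[rid] = coords[rid]["N"] + d / n if n > 0 else None
        else:
            h_pos[rid] = None
    return residues, coords, h_pos


def _ks_energy(n, h, c, o) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0  # overlapping atoms: not a physical H-bond geometry
    return _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_strands(structure: Structure, sel: DomainSelection,
                   domain_label: str | None = None) -> ElementMap:
    """Detect beta-strands from backbone H-bond ladders and label them A-G.

    A residue belongs to a strand when it participates in a Kabsch-Sander
    bridge (mutual or ladder-offset backbone H-bonds with energy below
    -0.5 kcal/mol to a residue at least 3 positions away).  Consecutive
    bridged residues form strands (single-residue bulges are absorbed);
    intervening residues are labelled by the flanking strands.
    """
    indices = select_domain(structure, sel)
    residues, bb, h_pos = _backbone_table(structure, indices)
    n_res = len(residues)
    if n_res < 6:
        raise ValueError("too few residues for strand detection")

    # donor i (N-H) -> acceptor j (C=O)
    hb = np.zeros((n_res, n_res), dtype=bool)
    for i in range(n_res):
        h = h_pos[residues[i]]
        if h is None:
            continue
        n = bb[residues[i]]["N"]
        for j in range(n_res):
            if abs(i - j) < 2:
                continue
            o = bb[residues[j]]["O"]
            if np.linalg.norm(o - n) > 5.2:  # K-S energy can't reach -0.5 beyond this
                continue
            c = bb[residues[j]]["C"]
            if _ks_energy(n, h, c, o) < _KS_CUTOFF:
                hb[i, j] = True

    in_bridge = np.zeros(n_res, dtype=bool)
    for i in range(n_res):
        for j in range(i + 3, n_res):
            anti = (hb[i, j] and hb[j, i]) or (
                0 < i and j + 1 < n_res and hb[i - 1, j + 1] and hb[j - 1, i + 1]
            )
            para = (0 < i and hb[i - 1, j] and hb[j, i + 1]) or (
                j + 1 < n_res and hb[j - 1, i] and hb[i, j + 1]
            )
            if anti or para:
                in_bridge[i] = in_bridge[j] = True

    # absorb single-residue bulges
    strand = in_bridge.copy()
    for i in range(1, n_res - 1):
        if not strand[i] and in_bridge[i - 1] and in_bridge[i + 1]:
            strand[i] = True

    # segment runs
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n_res:
        if strand[i]:
            j = i
            while j + 1 < n_res and strand[j + 1]:
                j += 1
            if j - i + 1 >= 2:  # a strand needs at least 2 residues
                segments.append((i, j))
            i = j + 1
        else:
            i += 1

    if len(segments) < 2:
        raise ValueError(f"only {len(segments)} strand(s) detected; not a beta-sheet domain")
    if len(segments) > len(STRAND_LABELS):
        raise ValueError(
            f"{len(segments)} strands detected, more than the {len(STRAND_LABELS)} "
            "the coarse-graining supports; provide a manual annotation file"
        )

    labels: dict[tuple[str, int, str], str] = {}
    for k, (lo, hi) in enumerate(segments):
        for i in range(lo, hi + 1):
            labels[residues[i]] = STRAND_LABELS[k]
    for i in range(segments[0][0]):
        labels[residues[i]] = "Nterm"
    for i in range(segments[-1][1] + 1, n_res):
        labels[residues[i]] = "Cterm"
    for k in range(len(segments) - 1):
        loop_label = STRAND_LABELS[k] + STRAND_LABELS[k + 1]
        for i in range(segments[k][1] + 1, segments[k + 1][0]):
            labels[residues[i]] = loop_label
    return ElementMap(domain_label=domain_label or sel.label, labels=labels)
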