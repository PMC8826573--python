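"""Coarse-grained contact statistics over strand/loop elements.

Residue-level contacts are aggregated onto element pairs (a-domain strand or
loop vs b-domain strand or loop).  The element-pair occurrence ratio is an
existence statistic: the fraction of frames in which at least one contact of
the kind joins the two elements (frame union over member residue pairs, not a
sum of per-residue ratios).  Interface classes (e.g. CH3-CH3 vs CH1-CL) are
compared through per-pair means with standard errors and through signed
difference maps normalized by the most frequent contact in either class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import KINDS, ContactRecord
from .elements import ElementMap

__all__ = [
    "ELEMENT_ORDER",
    "ContactFrequencyTable",
    "ClassSummary",
    "DifferenceMap",
    "coarse_grain",
    "class_average",
    "difference_map",
    "openbook_counts",
    "export_flare_json",
    "read_flare_json",
    "write_frequency_table",
    "element_marginals",
]

#: sequence order of coarse-graining units along the Ig fold
ELEMENT_ORDER = ("Nterm", "A", "AB", "B", "BC", "C", "CD", "D", "DE",
                 "E", "EF", "F", "FG", "G", "Cterm")


def _empty_matrix() -> pd.DataFrame:
    return pd.DataFrame(0.0, index=list(ELEMENT_ORDER), columns=list(ELEMENT_ORDER))


@dataclass
class ContactFrequencyTable:
    """Element-pair occurrence ratios for one system and contact kind."""

    system_id: str
    kind: str
    matrix: pd.DataFrame  # rows: a-domain elements, columns: b-domain elements

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("occurrence ratios must lie in [0, 1]")

    def ratio(self, element_a: str, element_b: str) -> float:
        return float(self.matrix.at[element_a, element_b])


@dataclass
class ClassSummary:
    """Per element-pair mean ratio and SEM across the systems of one class."""

    class_id: str
    kind: str
    mean: pd.DataFrame
    sem: pd.DataFrame
    n_systems: int

    def __post_init__(self) -> None:
        if self.n_systems < 1:
            raise ValueError("a class needs at least one system")
        if (self.sem.to_numpy() < 0).any():
            raise ValueError("SEM must be non-negative")


@dataclass
class DifferenceMap:
    """Signed, normalized difference between two class summaries.

    Entries are (mean1 - mean2) / max(mean over both classes); the map is
    antisymmetric under swapping the classes and bounded in [-1, 1].
    """

    kind: str
    matrix: pd.DataFrame
    normalizer: float

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if ((vals < -1 - 1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("difference-map entries must lie in [-1, 1]")


def coarse_grain(
    records: Iterable[ContactRecord],
    map_a: ElementMap,
    map_b: ElementMap,
    frame_count: int,
    system_id: str = "",
    kinds: Sequence[str] = KINDS,
) -> dict[str, ContactFrequencyTable]:
    """Aggregate a time-resolved contact table onto element pairs, per kind."""
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    frames: dict[str, dict[tuple[str, str], set[int]]] = {k: {} for k in kinds}
    for rec in records:
        if rec.kind not in frames:
            continue
        if rec.residue_a not in map_a:
            raise KeyError(f"residue {rec.residue_a} has no element label in domain a")
        if rec.residue_b not in map_b:
            raise KeyError(f"residue {rec.residue_b} has no element label in domain b")
        pair = (map_a.label_of(rec.residue_a), map_b.label_of(rec.residue_b))
        frames[rec.kind].setdefault(pair, set()).add(rec.frame)
    out: dict[str, ContactFrequencyTable] = {}
    for kind in kinds:
        matrix = _empty_matrix()
        for (ea, eb), fset in frames[kind].items():
            matrix.at[ea, eb] = len(fset) / frame_count
        out[kind] = ContactFrequencyTable(system_id=system_id, kind=kind, matrix=matrix)
    return out


def class_average(tables: Sequence[ContactFrequencyTable],
                  class_id: str = "") -> ClassSummary:
    """Mean ratio and SEM per element pair across member systems.

    SEM uses the sample standard deviation (n-1 denominator) divided by
    sqrt(n) and is 0 for a single system; element pairs missing from a system
    contribute 0 (absence of a contact is an observation).
    """
    if not tables:
        raise ValueError("class_average needs at least one table")
    kinds = {t.kind for t in tables}
    if len(kinds) > 1:
        raise ValueError(f"tables mix kinds: {sorted(kinds)}")
    stack = np.stack([t.matrix.to_numpy() for t in tables])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    template = tables[0].matrix
    return ClassSummary(
        class_id=class_id,
        kind=tables[0].kind,
        mean=pd.DataFrame(mean, index=template.index, columns=template.columns),
        sem=pd.DataFrame(sem, index=template.index, columns=template.columns),
        n_systems=n,
    )


def difference_map(s1: ClassSummary, s2: ClassSummary) -> DifferenceMap:
    """Signed per-pair difference of class means, normalized by the most
    frequent contact in either class."""
    if s1.kind != s2.kind:
        raise ValueError(f"kind mismatch: {s1.kind} vs {s2.kind}")
    if not s1.mean.index.equals(s2.mean.index) or not s1.mean.columns.equals(s2.mean.columns):
        raise ValueError("class summaries use different element label sets")
    normalizer = float(max(s1.mean.to_numpy().max(), s2.mean.to_numpy().max()))
    if normalizer <= 0:
        raise ValueError("both classes are all-zero; difference map undefined")
    return DifferenceMap(kind=s1.kind, matrix=(s1.mean - s2.mean) / normalizer,
                         normalizer=normalizer)


def openbook_counts(
    records: Iterable[ContactRecord],
    frame_count: int,
    kind: str | None = "saltbridge",
) -> dict[tuple[str, int, str], float]:
    """Duration-weighted interdomain contact count per residue, both domains.

    score(residue) = sum over its distinct partner residues of the occurrence
    ratio of that residue pair; written into the B-factor column for the
    open-book surface rendering.
    """
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    pair_frames: dict[tuple, set[int]] = {}
    for rec in records:
        if kind is not None and rec.kind != kind:
            continue
        pair_frames.setdefault((rec.residue_a, rec.residue_b), set()).add(rec.frame)
    scores: dict[tuple[str, int, str], float] = {}
    for (ra, rb), fset in pair_frames.items():
        ratio = len(fset) / frame_count
        scores[ra] = scores.get(ra, 0.0) + ratio
        scores[rb] = scores.get(rb, 0.0) + ratio
    return scores


def element_marginals(table: ContactFrequencyTable) -> tuple[pd.Series, pd.Series]:
    """Per-element marginal sums (a-domain rows, b-domain columns) for the
    per strand/loop barplots."""
    return table.matrix.sum(axis=1), table.matrix.sum(axis=0)


# ---------------------------------------------------------------------------
# exports


def export_flare_json(table: ContactFrequencyTable, path: str | Path) -> None:
    """Flareplot JSON: one edge per nonzero element pair, a_/b_ prefixes."""
    edges = []
    for ea in table.matrix.index:
        for eb in table.matrix.columns:
            w = float(table.matrix.at[ea, eb])
            if w > 0:
                edges.append({"name1": f"a_{ea}", "name2": f"b_{eb}", "weight": w})
    with open(path, "w") as fh:
        json.dump({"edges": edges}, fh, indent=1, sort_keys=True)


def read_flare_json(path: str | Path, system_id: str = "", kind: str = "") -> ContactFrequencyTable:
    with open(path) as fh:
        data = json.load(fh)
    matrix = _empty_matrix()
    for edge in data["edges"]:
        ea = edge["name1"].removeprefix("a_")
        eb = edge["name2"].removeprefix("b_")
        matrix.at[ea, eb] = float(edge["weight"])
    return ContactFrequencyTable(system_id=system_id, kind=kind, matrix=matrix)


def write_frequency_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated matrix with header row/column."""
    matrix.to_csv(path, sep="\t")
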