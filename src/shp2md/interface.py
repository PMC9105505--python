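"""Domain-domain interface mapping at a heavy-atom distance threshold.

A residue of one region is interfacial when its closest heavy atom lies
within a cutoff (default 5 A) of any heavy atom of the partner region.
Tracking the per-residue minimum distances over trajectory frames gives
the interface heat maps used to compare, e.g., the exon-6 region's
contacts with the N-SH2, C-SH2, and catalytic domains of SHP2. Linker
residues covalently joining the regions are excluded so the maps report
non-bonded contacts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import RegionMap, SelectionError, Structure, Trajectory

ResidueId = tuple[str, int]  # (chain, residue_number)

#: Residues excluded from interface maps by default: the N-SH2/C-SH2
#: linker (104-110) plus the covalent junction residues flanking the
#: exon-6 region (Gln214, Thr253).
DEFAULT_EXCLUSIONS: frozenset[ResidueId] = frozenset(
    {("A", r) for r in range(104, 111)} | {("A", 214), ("A", 253)}
)


def _region_heavy(
    structure: Structure,
    region: str | Iterable[ResidueId],
    region_map: RegionMap | None,
    exclude: frozenset[ResidueId] | set[ResidueId],
) -> tuple[list[int], list[ResidueId]]:
    """Indices of heavy atoms in the region and their residue ids."""
    if isinstance(region, str):
        if region_map is None:
            raise ValueError("a region name requires a region_map")
        residues = region_map.residues(region)
    else:
        residues = set(region)
    residues -= set(exclude)
    if not residues:
        raise SelectionError("region is empty after linker exclusion")
    idx, rids = [], []
    for i, a in enumerate(structure.atoms):
        rid = (a.chain, a.residue_number)
        if a.is_heavy and rid in residues:
            idx.append(i)
            rids.append(rid)
    if not idx:
        raise SelectionError("region matches no heavy atoms in structure")
    return idx, rids


def residue_min_distances(
    frame: Structure,
    region_a: str | Iterable[ResidueId],
    region_b: str | Iterable[ResidueId],
    region_map: RegionMap | None = None,
    exclude: Iterable[ResidueId] = DEFAULT_EXCLUSIONS,
) -> dict[ResidueId, float]:
    """Min heavy-atom distance from each region_a residue to region_b.

    Uses a k-d tree over the partner region's heavy atoms; the map covers
    every region_a residue regardless of threshold (thresholding is the
    caller's concern).
    """
    exclude = frozenset(exclude)
    idx_a, rids_a = _region_heavy(frame, region_a, region_map, exclude)
    idx_b, _ = _region_heavy(frame, region_b, region_map, exclude)
    if set(rids_a) & {
        (frame.atoms[i].chain, frame.atoms[i].residue_number) for i in idx_b
    }:
        raise ValueError("regions overlap; interface is undefined")
    coords = frame.coords
    tree = cKDTree(coords[idx_b])
    d, _ = tree.query(coords[idx_a])
    out: dict[ResidueId, float] = {}
    for rid, dist in zip(rids_a, d):
        if rid not in out or dist < out[rid]:
            out[rid] = float(dist)
    return out


def interfacial_residues(
    frame: Structure,
    region_a: str | Iterable[ResidueId],
    region_b: str | Iterable[ResidueId],
    threshold: float = 5.0,
    region_map: RegionMap | None = None,
    exclude: Iterable[ResidueId] = DEFAULT_EXCLUSIONS,
) -> dict[ResidueId, float]:
    """Residues of region_a within ``threshold`` of region_b heavy atoms.

    The symmetric call (swapping the regions) gives the partner side of
    the interface; hydrogens never participate.
    """
    dists = residue_min_distances(frame, region_a, region_b, region_map, exclude)
    return {rid: d for rid, d in dists.items() if d <= threshold}


@dataclass
class InterfaceMap:
    """Per-residue minimum-distance matrix over time (one region's side).

    Rows are the residues of ``region_a`` that are interfacial
    (min distance <= threshold) in at least one analyzed column; column 0
    may hold a reference crystal structure. Cells above ``cap`` are
    reported as absent in the TSV export.
    """

    region_a: str
    region_b: str
    rows: list[ResidueId]
    times: np.ndarray  # NaN in slot 0 marks a reference column
    matrix: np.ndarray  # (n_rows, n_cols) min distances, A
    threshold: float
    cap: float = 10.0
    column_labels: list[str] = field(default_factory=list)

    def occupancy(self) -> dict[ResidueId, float]:
        """Fraction of columns in which each row residue is interfacial."""
        frac = (self.matrix <= self.threshold).mean(axis=1)
        return {rid: float(f) for rid, f in zip(self.rows, frac)}

    def classify(self, stable_fraction: float = 0.5) -> dict[ResidueId, str]:
        """'stable' if interfacial in >= stable_fraction of columns, else
        'transient' (interfacial in at least one column by construction)."""
        return {
            rid: ("stable" if f >= stable_fraction else "transient")
            for rid, f in self.occupancy().items()
        }

    def to_tsv(self, path: str | Path) -> None:
        header = ["residue"] + self.column_labels
        lines = [
            f"# interface {self.region_a} vs {self.region_b}; "
            f"threshold {self.threshold} A; cap {self.cap} A",
            "\t".join(header),
        ]
        for rid, row in zip(self.rows, self.matrix):
            cells = [f"{d:.3f}" if d <= self.cap else "absent" for d in row]
            lines.append("\t".join([f"{rid[0]}{rid[1]}"] + cells))
        Path(path).write_text("\n".join(lines) + "\n")


def interface_heatmap(
    trajectory: Trajectory,
    region_a: str | Iterable[ResidueId],
    region_b: str | Iterable[ResidueId],
    threshold: float = 5.0,
    region_map: RegionMap | None = None,
    exclude: Iterable[ResidueId] = DEFAULT_EXCLUSIONS,
    reference: Structure | None = None,
    cap: float = 10.0,
) -> InterfaceMap:
    """Interface heat map: rows = union of interfacial residues over frames.

    When a reference structure is supplied (e.g. the parent crystal
    structure) it occupies column 0, so the map reads as "time = 0 is the
    crystal, then the simulation".
    """
    columns: list[dict[ResidueId, float]] = []
    labels: list[str] = []
    times: list[float] = []
    if reference is not None:
        columns.append(
            residue_min_distances(reference, region_a, region_b, region_map, exclude)
        )
        labels.append(reference.label or "reference")
        times.append(np.nan)
    for t, frame in zip(trajectory.times, trajectory.frames):
        columns.append(
            residue_min_distances(frame, region_a, region_b, region_map, exclude)
        )
        labels.append(f"{t:g}ns")
        times.append(float(t))
    rows = sorted(
        {
            rid
            for col in columns
            for rid, d in col.items()
            if d <= threshold
        }
    )
    big = np.inf
    matrix = np.full((len(rows), len(columns)), big)
    for j, col in enumerate(columns):
        for i, rid in enumerate(rows):
            if rid in col:
                matrix[i, j] = col[rid]
    name_a = region_a if isinstance(region_a, str) else "region_a"
    name_b = region_b if isinstance(region_b, str) else "region_b"
    return InterfaceMap(
        region_a=name_a,
        region_b=name_b,
        rows=rows,
        times=np.array(times),
        matrix=matrix,
        threshold=threshold,
        cap=cap,
        column_labels=labels,
    )


def surface_distance_coloring(
    frame: Structure,
    region: str | Iterable[ResidueId],
    partner: str | Iterable[ResidueId],
    cap: float = 10.0,
    region_map: RegionMap | None = None,
    exclude: Iterable[ResidueId] = frozenset(),
) -> Structure:
    """Annotate region atoms with min distance to partner heavy atoms.

    Distances are clipped at ``cap`` and stored in the B-factor column of
    the returned region sub-structure, ready for surface rendering by any
    external viewer.
    """
    exclude = frozenset(exclude)
    idx_r, _ = _region_heavy(frame, region, region_map, exclude)
    idx_p, _ = _region_heavy(frame, partner, region_map, exclude)
    coords = frame.coords
    tree = cKDTree(coords[idx_p])
    d, _ = tree.query(coords[idx_r])
    sub = frame.subset(idx_r, label=f"{frame.label}|distance-colored")
    return sub.with_bfactors(np.minimum(d, cap))
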