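"""Rigid-body superposition and per-frame geometric observables.

The loop-separation observables tracked here are the field's standard
probes of the N-SH2 conformational state: the Gly67(CA)-Asn92(CA)
distance separates the EF and BG loops that gate the phosphotyrosine
peptide cleft (about 8 A closed versus about 15 A open), and companion
distances (Pro38 CA-Thr59 CA, Thr59 N-Tyr62 O, Lys55 O-Tyr66 N,
Ser36 CA-Lys55 CA) trace the 34-40 and D'E loop rearrangements that
accompany the transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .structure_io import (
    Atom,
    AtomIdentity,
    SelectionError,
    Structure,
    Trajectory,
    backbone_predicate,
    ca_predicate,
    predicate_mask,
)

AtomPredicate = Callable[[Atom], bool]


@dataclass
class DistanceSeries:
    """Per-frame scalar distance between a fixed atom pair, Angstroms."""

    observable_name: str
    times: np.ndarray
    values: np.ndarray
    atom_pair: tuple[AtomIdentity, AtomIdentity]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def window(self, t_min: float, t_max: float) -> "DistanceSeries":
        mask = (self.times >= t_min) & (self.times <= t_max)
        if not mask.any():
            raise ValueError(f"no samples in window [{t_min}, {t_max}] ns")
        return DistanceSeries(
            self.observable_name, self.times[mask], self.values[mask], self.atom_pair
        )

    def to_tsv(self, path: str | Path) -> None:
        write_series_tsv(path, self.times, self.values, self.observable_name)


@dataclass
class RmsdSeries:
    """Per-frame RMSD against a fixed reference after optimal alignment."""

    selection_name: str
    times: np.ndarray
    values: np.ndarray
    reference_label: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")

    def to_tsv(self, path: str | Path) -> None:
        write_series_tsv(
            path, self.times, self.values,
            f"rmsd[{self.selection_name}] vs {self.reference_label}",
        )


def write_series_tsv(
    path: str | Path, times: np.ndarray, values: np.ndarray, name: str
) -> None:
    """One observable per file: time_ns <TAB> value."""
    lines = [f"# {name}", "time_ns\tvalue"]
    lines += [f"{t:.6g}\t{v:.6f}" for t, v in zip(times, values)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R@x + t ~ ref.

    Standard SVD solution of the orthogonal Procrustes problem with the
    determinant sign correction, so a reflection is never returned even
    for degenerate (e.g. collinear) point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    h = (mobile - mu_m).T @ (reference - mu_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    return rot, trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Unweighted root-mean-square deviation of paired coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _selection_indices(
    structure: Structure, selection: AtomPredicate | Sequence[AtomIdentity] | str
) -> list[int]:
    if isinstance(selection, str):
        preset = {"backbone": backbone_predicate, "ca": ca_predicate}.get(selection)
        if preset is None:
            raise ValueError(f"unknown selection preset {selection!r}")
        selection = preset
    if callable(selection):
        return np.nonzero(predicate_mask(structure, selection))[0].tolist()
    return [structure.index_of(ident) for ident in selection]


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: AtomPredicate | Sequence[AtomIdentity] | str = "backbone",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of matched selected atoms.

    Atoms are paired by (residue_number, atom name); both structures must
    expose identical selected identity lists up to chain id. Returns the
    proper rotation, translation, and the post-fit RMSD over the
    selection.
    """
    idx_m = _selection_indices(mobile, selection)
    idx_r = _selection_indices(reference, selection)
    key_m = [(mobile.atoms[i].residue_number, mobile.atoms[i].name) for i in idx_m]
    key_r = [(reference.atoms[i].residue_number, reference.atoms[i].name) for i in idx_r]
    if key_m != key_r:
        missing = set(key_m) ^ set(key_r)
        raise SelectionError(
            f"selected atoms do not match between structures; differing: "
            f"{sorted(missing)[:8]}"
        )
    if len(idx_m) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    xm = np.array([mobile.atoms[i].position for i in idx_m])
    xr = np.array([reference.atoms[i].position for i in idx_r])
    rot, trans = kabsch(xm, xr)
    fitted = xm @ rot.T + trans
    return rot, trans, rmsd(fitted, xr)


def rmsd_series(
    trajectory: Trajectory,
    reference: Structure,
    selection: AtomPredicate | Sequence[AtomIdentity] | str = "backbone",
    align_selection: AtomPredicate | Sequence[AtomIdentity] | str | None = None,
    selection_name: str = "backbone",
) -> RmsdSeries:
    """Per-frame RMSD versus an arbitrary reference structure.

    Each frame is first superposed on ``align_selection`` (defaults to
    the reporting selection), then the RMSD is taken over ``selection``.
    Atom pairing is by (residue_number, atom name), so the reference may
    be a different crystal structure of the same domain — e.g. the open
    N-SH2 conformation — rather than the trajectory's own first frame.
    """
    if align_selection is None:
        align_selection = selection
    topo = trajectory.topology
    idx_sel_m = _selection_indices(topo, selection)
    idx_aln_m = _selection_indices(topo, align_selection)

    def _match(idx_mobile: list[int]) -> tuple[list[int], list[int]]:
        ref_by_key = {
            (a.residue_number, a.name): i for i, a in enumerate(reference.atoms)
        }
        pairs_m, pairs_r = [], []
        unmatched = []
        for i in idx_mobile:
            key = (topo.atoms[i].residue_number, topo.atoms[i].name)
            j = ref_by_key.get(key)
            if j is None:
                unmatched.append(key)
            else:
                pairs_m.append(i)
                pairs_r.append(j)
        if unmatched:
            raise SelectionError(
                f"atoms absent from reference {reference.label!r}: {unmatched[:8]}"
            )
        return pairs_m, pairs_r

    sel_m, sel_r = _match(idx_sel_m)
    aln_m, aln_r = _match(idx_aln_m)
    ref_coords = reference.coords
    values = np.empty(len(trajectory))
    for k, frame in enumerate(trajectory.frames):
        coords = frame.coords
        rot, trans = kabsch(coords[aln_m], ref_coords[aln_r])
        fitted = coords[sel_m] @ rot.T + trans
        values[k] = rmsd(fitted, ref_coords[sel_r])
    return RmsdSeries(selection_name, trajectory.times.copy(), values,
                      reference.label or "reference")


def per_residue_rmsd(
    trajectory: Trajectory,
    reference: Structure,
    align_selection: AtomPredicate | Sequence[AtomIdentity] | str = "backbone",
) -> dict[tuple[str, int], float]:
    """CA RMSD per residue after alignment, for ribbon-thickness plots."""
    topo = trajectory.topology
    aln_m = _selection_indices(topo, align_selection)
    ref_by_key = {(a.residue_number, a.name): i for i, a in enumerate(reference.atoms)}
    aln_pairs = [
        (i, ref_by_key[(topo.atoms[i].residue_number, topo.atoms[i].name)])
        for i in aln_m
        if (topo.atoms[i].residue_number, topo.atoms[i].name) in ref_by_key
    ]
    if len(aln_pairs) < 3:
        raise SelectionError("fewer than 3 alignment atoms matched in reference")
    am = [p[0] for p in aln_pairs]
    ar = [p[1] for p in aln_pairs]
    ca_idx = [
        (i, ref_by_key.get((a.residue_number, "CA")))
        for i, a in enumerate(topo.atoms)
        if a.name == "CA"
    ]
    ca_idx = [(i, j) for i, j in ca_idx if j is not None]
    ref_coords = reference.coords
    sq = {i: 0.0 for i, _ in ca_idx}
    for frame in trajectory.frames:
        coords = frame.coords
        rot, trans = kabsch(coords[am], ref_coords[ar])
        for i, j in ca_idx:
            d = coords[i] @ rot.T + trans - ref_coords[j]
            sq[i] += float(d @ d)
    n = len(trajectory)
    return {
        (topo.atoms[i].chain, topo.atoms[i].residue_number): float(
            np.sqrt(sq[i] / n)
        )
        for i, _ in ca_idx
    }


def distance_series(
    trajectory: Trajectory,
    pair: tuple[AtomIdentity, AtomIdentity],
    name: str | None = None,
) -> DistanceSeries:
    """Euclidean distance between two named atoms, per frame."""
    ident_a, ident_b = pair
    topo = trajectory.topology
    ia = topo.index_of(ident_a)
    ib = topo.index_of(ident_b)
    coords = trajectory.coords()
    values = np.linalg.norm(coords[:, ia, :] - coords[:, ib, :], axis=1)
    if name is None:
        name = (
            f"{ident_a[0]}{ident_a[1]}({ident_a[2]})-"
            f"{ident_b[0]}{ident_b[1]}({ident_b[2]})"
        )
    return DistanceSeries(name, trajectory.times.copy(), values, (ident_a, ident_b))
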