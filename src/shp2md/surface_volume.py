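"""Molecular surface areas and the phosphopeptide-groove volume.

Areas use Shrake-Rupley quadrature on a deterministic Fibonacci sphere
lattice. The buried interface area between two regions is the standard
half-difference

    buried = (A_region_a + A_region_b - A_complex) / 2,

with the regions' surfaces computed in isolation and in the two-region
complex. The default probe radius is 0 (van der Waals surface, the
quantity the interface-area comparison is defined on); pass 1.4 A for a
water-probe SASA.

The groove volume between the EF and BG loops of an SH2 domain is a
grid estimate: count grid cells inside a cylindrical envelope spanned
between the two loops' CA centroids, outside every atom sphere, and
solvent-connected to the envelope boundary (a 6-neighbor flood fill, so
sealed interior voids are not counted as groove).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import RegionMap, SelectionError, Structure, Trajectory

ResidueId = tuple[str, int]


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points on the Fibonacci lattice."""
    if n_points < 32:
        raise ValueError("need at least 32 quadrature points")
    i = np.arange(n_points) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_arrays(
    structure: Structure, indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    coords = structure.coords[list(indices)]
    radii = np.array([structure.atoms[i].vdw_radius for i in indices])
    return coords, radii


def sphere_surface_area(
    frame: Structure,
    selection: Sequence[int] | None = None,
    probe_radius: float = 0.0,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley exposed area per selected atom, Angstrom^2.

    For each atom, the fraction of ``n_points`` lattice points on the
    inflated sphere (radius vdw + probe) that fall outside every
    neighbor's inflated sphere, times 4 pi (r + p)^2. probe_radius = 0
    gives the van der Waals surface; 1.4 the water-probe SASA.
    """
    if selection is None:
        selection = [i for i, a in enumerate(frame.atoms) if a.is_heavy]
    if len(selection) == 0:
        raise SelectionError("empty selection for surface area")
    coords, radii = _atom_arrays(frame, selection)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0 * float(inflated.max()), output_type="ndarray")
    for i, j in pairs:
        if np.linalg.norm(coords[i] - coords[j]) < 1e-9:
            a, b = frame.atoms[selection[i]], frame.atoms[selection[j]]
            raise ValueError(
                f"coincident atom centers: {a.identity} and {b.identity}"
            )
    neighbors: list[list[int]] = [[] for _ in selection]
    for i, j in pairs:
        if np.linalg.norm(coords[i] - coords[j]) < inflated[i] + inflated[j]:
            neighbors[i].append(j)
            neighbors[j].append(i)
    lattice = fibonacci_sphere(n_points)
    areas = np.empty(len(selection))
    for i in range(len(selection)):
        pts = coords[i] + inflated[i] * lattice
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors[i]:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= inflated[j] ** 2
        areas[i] = exposed.mean() * 4.0 * math.pi * inflated[i] ** 2
    return areas


@dataclass
class AreaResult:
    """Surface areas of two regions, their complex, and the buried area."""

    a_region_a: float
    a_region_b: float
    a_complex: float
    buried: float
    probe_radius: float
    n_sphere_points: int


def buried_area(
    frame: Structure,
    region_a: str | Iterable[ResidueId],
    region_b: str | Iterable[ResidueId],
    probe_radius: float = 0.0,
    n_points: int = 960,
    region_map: RegionMap | None = None,
) -> AreaResult:
    """Interface area buried between two disjoint regions.

    Heavy atoms only. ``buried = (A_a + A_b - A_complex)/2`` holds
    identically by construction; it is zero (up to quadrature noise) for
    regions beyond contact range.
    """

    def _indices(region: str | Iterable[ResidueId]) -> list[int]:
        if isinstance(region, str):
            if region_map is None:
                raise ValueError("a region name requires a region_map")
            residues = region_map.residues(region)
        else:
            residues = set(region)
        idx = [
            i
            for i, a in enumerate(frame.atoms)
            if a.is_heavy and (a.chain, a.residue_number) in residues
        ]
        if not idx:
            raise SelectionError("region matches no heavy atoms")
        return idx

    idx_a = _indices(region_a)
    idx_b = _indices(region_b)
    if set(idx_a) & set(idx_b):
        raise ValueError("regions overlap; buried area is undefined")

    def _total(indices: list[int]) -> float:
        sub = frame.subset(indices)
        return float(
            np.sum(sphere_surface_area(sub, None, probe_radius, n_points))
        )

    a_a = _total(idx_a)
    a_b = _total(idx_b)
    a_ab = _total(sorted(idx_a + idx_b))
    return AreaResult(
        a_region_a=a_a,
        a_region_b=a_b,
        a_complex=a_ab,
        buried=0.5 * (a_a + a_b - a_ab),
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


# ---------------------------------------------------------------------------
# Groove volume


def _loop_ca_centroid(
    frame: Structure, loop: str | Iterable[ResidueId], region_map: RegionMap | None
) -> np.ndarray:
    if isinstance(loop, str):
        if region_map is None:
            raise ValueError("a region name requires a region_map")
        residues = region_map.residues(loop)
    else:
        residues = set(loop)
    pts = [
        a.position
        for a in frame.atoms
        if a.name == "CA" and (a.chain, a.residue_number) in residues
    ]
    if not pts:
        raise SelectionError("loop selection has no CA atoms")
    return np.mean(pts, axis=0)


def groove_volume(
    frame: Structure,
    mouth_a: str | Iterable[ResidueId] = "EF_loop",
    mouth_b: str | Iterable[ResidueId] = "BG_loop",
    grid_spacing: float = 0.5,
    probe_radius: float = 0.0,
    envelope_radius: float = 6.0,
    margin: float = 0.0,
    region_map: RegionMap | None = None,
) -> float:
    """Grid volume (A^3) of the open groove between two loop mouths.

    The envelope is a finite cylinder around the axis joining the CA
    centroids of the two mouth loops, of radius ``envelope_radius``,
    extended axially by ``margin`` at each end (a negative margin
    shortens it). A cell counts toward the volume when its center lies
    inside the envelope, outside every atom sphere (vdw + probe), and in
    an empty component connected to the envelope boundary — sealed
    interior voids are excluded. Deterministic for a fixed grid.
    """
    ca = _loop_ca_centroid(frame, mouth_a, region_map)
    cb = _loop_ca_centroid(frame, mouth_b, region_map)
    axis = cb - ca
    length = float(np.linalg.norm(axis))
    if length < 1e-6:
        raise ValueError("mouth centroids coincide; groove axis is undefined")
    u = axis / length

    lo_t, hi_t = -margin, length + margin
    if hi_t <= lo_t:
        raise ValueError("margin collapses the envelope")
    # grid bounding box of the cylinder
    corners = []
    for t in (lo_t, hi_t):
        center = ca + t * u
        corners.append(center - envelope_radius)
        corners.append(center + envelope_radius)
    corners = np.array(corners)
    lo = corners.min(axis=0)
    hi = corners.max(axis=0)
    n = np.maximum(1, np.ceil((hi - lo) / grid_spacing).astype(int))
    axes = [lo[k] + (np.arange(n[k]) + 0.5) * grid_spacing for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    rel = pts - ca
    t = rel @ u
    radial2 = np.sum(rel * rel, axis=1) - t * t
    inside = (t >= lo_t) & (t <= hi_t) & (radial2 <= envelope_radius**2)
    inside = inside.reshape(n)

    heavy = [i for i, a in enumerate(frame.atoms) if a.is_heavy]
    coords, radii = _atom_arrays(frame, heavy)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    occupied = np.zeros(pts.shape[0], dtype=bool)
    hits = tree.query_ball_point(pts, r=float(inflated.max()))
    for k, hit in enumerate(hits):
        if hit:
            d = np.linalg.norm(coords[hit] - pts[k], axis=1)
            occupied[k] = bool(np.any(d < inflated[hit]))
    occupied = occupied.reshape(n)

    empty = inside & ~occupied
    labels, n_lab = ndimage.label(empty, structure=ndimage.generate_binary_structure(3, 1))
    if n_lab == 0:
        return 0.0
    # envelope-boundary cells: inside cells with a 6-neighbor outside the
    # envelope (or on the grid edge)
    interior = ndimage.binary_erosion(
        inside, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    boundary = inside & ~interior
    open_labels = np.unique(labels[boundary & empty])
    open_labels = open_labels[open_labels > 0]
    count = int(np.isin(labels, open_labels).sum())
    return count * grid_spacing**3


@dataclass
class VolumeSeries:
    """Groove volume snapshots over time."""

    times: np.ndarray
    volumes: np.ndarray
    grid_spacing: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")

    @property
    def mean(self) -> float:
        return float(np.mean(self.volumes))

    @property
    def sd(self) -> float:
        return float(np.std(self.volumes, ddof=1)) if len(self.volumes) > 1 else 0.0

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# groove volume, grid {self.grid_spacing} A", "time_ns\tvolume_A3"]
        lines += [f"{t:.6g}\t{v:.3f}" for t, v in zip(self.times, self.volumes)]
        lines.append(f"# mean\t{self.mean:.3f}")
        lines.append(f"# sd\t{self.sd:.3f}")
        Path(path).write_text("\n".join(lines) + "\n")


def volume_series_average(
    trajectory: Trajectory,
    window: tuple[float, float] = (3.0, 30.0),
    stride_ns: float = 1.0,
    **groove_kwargs,
) -> VolumeSeries:
    """Groove volume at snapshots every ``stride_ns`` across ``window``.

    Mirrors the snapshot-averaging scheme used for pocket volumes in
    equilibrated trajectories: one conformer per nanosecond from the end
    of equilibration to the end of the run (28 snapshots for 3-30 ns).
    """
    t0, t1 = window
    if t0 < trajectory.times[0] - 1e-9 or t1 > trajectory.times[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] ns exceeds trajectory extent "
            f"[{trajectory.times[0]:g}, {trajectory.times[-1]:g}] ns"
        )
    targets = np.arange(t0, t1 + 1e-9, stride_ns)
    idx = [int(np.argmin(np.abs(trajectory.times - t))) for t in targets]
    times = trajectory.times[idx]
    vols = np.array(
        [groove_volume(trajectory.frames[i], **groove_kwargs) for i in idx]
    )
    return VolumeSeries(times, vols, groove_kwargs.get("grid_spacing", 0.5))
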