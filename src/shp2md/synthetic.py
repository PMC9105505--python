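"""Synthetic structures and trajectories with exactly known ground truth.

Nothing here is physically realistic: the generators exist so that every
analysis stage — interface mapping, buried areas, groove volumes,
loop-separation deconvolution, cation-pi detection — can be validated
against planted values without running molecular dynamics or downloading
structures. Pseudo-residues use standard protein atom names (CA, N, O,
NZ, tyrosine ring atoms) so all selectors work unchanged.

Key generators:

* :func:`make_clamp_structure` — two rigid atom walls flanking a cavity
  of closed-form volume, a toy analog of the BG/EF loop groove.
* :func:`make_two_domain_complex` — two compact pseudo-domains at an
  exact heavy-atom gap, optionally bridged by a small "strap" segment
  (the exon-6-like bridging arrangement).
* :func:`make_sh2_like_domain` — a SYNTHETIC stand-in for an N-SH2
  conformer carrying all the marker residues of the real domain, with
  the EF/BG loop separation planted exactly (8.2 A reproduces the closed
  crystal arrangement, 14.8 A the open one).
* :func:`sample_trajectory` — multi-frame ensembles whose loop
  separation follows a prescribed Gaussian mixture and whose
  lysine/tyrosine cation-pi geometry is satisfied in an exact fraction
  of frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import Atom, RegionMap, Structure, Trajectory

CHAIN = "A"


def _atom(
    serial: int,
    name: str,
    element: str,
    res_name: str,
    res_num: int,
    pos: Sequence[float],
    radius: float = 1.70,
) -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=res_name,
        residue_number=res_num,
        chain=CHAIN,
        position=np.asarray(pos, dtype=float),
        vdw_radius=radius,
    )


# ---------------------------------------------------------------------------
# Clamp fixture with analytic cavity volume


def _wall_xy_positions(
    wall_extent: float, wall_spacing: float, envelope_radius: float, atom_radius: float
) -> list[tuple[float, float]]:
    """Square-grid wall positions, skipping the rim annulus.

    Positions whose radial distance from the axis falls within
    (R - r, R + r) would clip the cylindrical envelope and break the
    closed-form volume, so they are omitted (the flood fill does not
    depend on the walls being gap-free).
    """
    n = int(wall_extent // wall_spacing)
    coords = [wall_spacing * k for k in range(-n, n + 1)]
    out = []
    for x in coords:
        for y in coords:
            rho = math.hypot(x, y)
            if envelope_radius - atom_radius < rho < envelope_radius + atom_radius:
                continue
            out.append((x, y))
    return out


def make_clamp_structure(
    mouth_separation: float,
    envelope_radius: float = 6.0,
    wall_atom_radius: float = 1.70,
    wall_spacing: float = 4.0,
    wall_extent: float = 10.0,
    label: str | None = None,
) -> Structure:
    """Two parallel atom walls flanking an open cavity (groove analog).

    Designated CA atoms (residues 67 and 92, mimicking the EF/BG marker
    residues) sit at the wall centers, exactly ``mouth_separation`` A
    apart; :func:`clamp_analytic_volume` gives the exact cavity volume
    inside the standard cylindrical envelope for the same parameters.
    """
    if mouth_separation <= 2.0 * wall_atom_radius:
        raise ValueError("walls overlap at this separation")
    if wall_spacing < 2.0 * wall_atom_radius:
        raise ValueError("wall atoms would overlap; increase wall_spacing")
    s = float(mouth_separation)
    atoms: list[Atom] = []
    serial = 1
    ef_res = (66, 67, 68)
    bg_res = (89, 90, 91, 92)
    for z, res_cycle, marker_res in ((0.0, ef_res, 67), (s, bg_res, 92)):
        k = 0
        for x, y in _wall_xy_positions(
            wall_extent, wall_spacing, envelope_radius, wall_atom_radius
        ):
            if x == 0.0 and y == 0.0:
                atoms.append(
                    _atom(serial, "CA", "C", "GLY", marker_res, (x, y, z),
                          wall_atom_radius)
                )
            else:
                res = res_cycle[k % len(res_cycle)]
                atoms.append(
                    _atom(serial, f"C{k}", "C", "WAL", res, (x, y, z),
                          wall_atom_radius)
                )
                k += 1
            serial += 1
    return Structure(atoms, label or f"synthetic-clamp-{s:g}A")


def clamp_analytic_volume(
    mouth_separation: float,
    envelope_radius: float = 6.0,
    wall_atom_radius: float = 1.70,
    wall_spacing: float = 4.0,
    wall_extent: float = 10.0,
) -> float:
    """Exact cavity volume of the clamp inside the cylindrical envelope.

    The envelope is the cylinder of radius R between the two wall planes;
    each wall atom whose center lies at radial distance <= R - r intrudes
    exactly a half-ball (walls are non-overlapping by construction):

        V = pi R^2 s - n_inside * (2/3) pi r^3.
    """
    r = wall_atom_radius
    big_r = envelope_radius
    s = mouth_separation
    positions = _wall_xy_positions(wall_extent, wall_spacing, big_r, r)
    n_inside = 2 * sum(1 for x, y in positions if math.hypot(x, y) <= big_r - r)
    return math.pi * big_r**2 * s - n_inside * (2.0 / 3.0) * math.pi * r**3


#: Region map matching the clamp's marker residues.
def clamp_region_map() -> RegionMap:
    return RegionMap({"EF_loop": [(CHAIN, 66, 68)], "BG_loop": [(CHAIN, 89, 92)]})


# ---------------------------------------------------------------------------
# Two-domain complex with exact interfacial gap


def make_two_domain_complex(
    gap: float,
    n_res_a: int = 6,
    n_res_b: int = 6,
    with_e6_strap: bool = False,
    label: str | None = None,
) -> Structure:
    """Two compact pseudo-domains at an exact closest heavy-atom gap.

    Domain A (residues 1..n_res_a) extends toward -x with its frontier
    CA at the origin; domain B (residues 253..) extends toward +x with
    its frontier CA at (gap, 0, 0), so the minimum heavy-atom distance
    between the domains is ``gap`` exactly. The optional strap (residues
    215-217) arches over the gap and contacts both domains within 5 A,
    emulating a bridging peptide.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    step = 3.8
    atoms: list[Atom] = []
    serial = 1
    for i in range(n_res_a):
        x = -step * i
        atoms.append(_atom(serial, "CA", "C", "ALA", i + 1, (x, 0.0, 0.0)))
        serial += 1
        atoms.append(_atom(serial, "N", "N", "ALA", i + 1, (x, 1.5, 0.0)))
        serial += 1
    for j in range(n_res_b):
        x = gap + step * j
        atoms.append(_atom(serial, "CA", "C", "VAL", 253 + j, (x, 0.0, 0.0)))
        serial += 1
        atoms.append(_atom(serial, "N", "N", "VAL", 253 + j, (x, 1.5, 0.0)))
        serial += 1
    if with_e6_strap:
        mid = gap / 2.0
        strap = [
            (215, (0.0, 4.0, 0.0)),
            (216, (mid, 5.5, 0.0)),
            (217, (gap, 4.0, 0.0)),
        ]
        for res, pos in strap:
            atoms.append(_atom(serial, "CA", "C", "GLY", res, pos))
            serial += 1
    return Structure(atoms, label or f"synthetic-two-domain-{gap:g}A")


def two_domain_region_map(n_res_a: int = 6, n_res_b: int = 6) -> RegionMap:
    return RegionMap(
        {
            "domain_a": [(CHAIN, 1, n_res_a)],
            "domain_b": [(CHAIN, 253, 253 + n_res_b - 1)],
            "strap": [(CHAIN, 215, 217)],
        }
    )


def sample_two_domain_trajectory(
    gaps: Sequence[float],
    dt: float = 1.0,
    t0: float = 0.0,
    **complex_kwargs,
) -> Trajectory:
    """Trajectory of two-domain complexes at prescribed per-frame gaps."""
    frames = [make_two_domain_complex(g, **complex_kwargs) for g in gaps]
    times = [t0 + dt * i for i in range(len(frames))]
    return Trajectory(frames, times)


# ---------------------------------------------------------------------------
# SH2-like domain stand-in

#: Crystallographic EF/BG loop separations of the closed and open N-SH2
#: conformations (Gly67 CA - Asn92 CA), Angstroms.
CLOSED_LOOP_SEPARATION = 8.2
OPEN_LOOP_SEPARATION = 14.8

LOOP_AXIS = np.array([1.0, 0.0, 0.0])


def make_sh2_like_domain(
    loop_separation: float = CLOSED_LOOP_SEPARATION,
    cation_pi: tuple[float, float] | None = (5.0, 20.0),
    label: str | None = None,
) -> Structure:
    """SYNTHETIC stand-in for an N-SH2 domain conformer.

    This is not a real structure: it is a sparse pseudo-domain carrying
    the marker atoms of the residues used by every distance observable
    of the analysis (Ser36, Pro38, Asp40, Lys55, Gln57, Thr59, Tyr62,
    Tyr66 with a full aromatic ring, Gly67, Asn92), arranged so that the
    EF/BG loop separation (Gly67 CA - Asn92 CA) equals
    ``loop_separation`` exactly. With the defaults 8.2 A and 14.8 A it
    reproduces the loop separations of the closed and open crystal
    conformations by construction. ``cation_pi`` plants the lysine
    NZ / tyrosine-ring geometry at an exact (L, theta).
    """
    d = float(loop_separation)
    atoms: list[Atom] = []
    serial = [0]

    def add(name: str, element: str, res_name: str, res: int, pos) -> None:
        serial[0] += 1
        atoms.append(_atom(serial[0], name, element, res_name, res, pos))

    # marker loop atoms: EF loop anchor at origin, BG loop along +x
    add("CA", "C", "GLY", 67, (0.0, 0.0, 0.0))
    add("CA", "C", "ASN", 92, (d, 0.0, 0.0))
    # 34-40 loop markers
    add("CA", "C", "SER", 36, (2.0, 9.0, 3.0))
    add("CA", "C", "PRO", 38, (4.0, 10.5, 2.0))
    add("CA", "C", "ASP", 40, (6.0, 9.5, 1.0))
    # beta strand with Lys55 / Gln57
    add("N", "N", "LYS", 55, (1.0, 5.2, 0.5))
    add("CA", "C", "LYS", 55, (2.0, 4.6, 0.0))
    add("C", "C", "LYS", 55, (3.1, 5.0, -0.8))
    add("O", "O", "LYS", 55, (3.4, 6.2, -0.9))
    add("CA", "C", "GLN", 57, (5.5, 4.0, -1.0))
    # D'E loop: Thr59 and Tyr62 backbone markers
    add("N", "N", "THR", 59, (7.5, 3.0, 0.5))
    add("CA", "C", "THR", 59, (8.5, 2.5, 1.2))
    add("CA", "C", "TYR", 62, (10.0, 1.0, 0.5))
    add("O", "O", "TYR", 62, (10.8, 1.8, 1.3))
    # Tyr66: backbone near EF loop plus an aromatic ring
    add("N", "N", "TYR", 66, (0.5, 1.8, 1.0))
    add("CA", "C", "TYR", 66, (-0.5, 2.5, 1.5))
    ring_center = np.array([-1.5, 4.5, 2.0])
    ring_radius = 1.39
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, math.cos(math.radians(30)), math.sin(math.radians(30))])
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    for k, name in enumerate(ring_names):
        ang = math.radians(60.0 * k)
        pos = ring_center + ring_radius * (math.cos(ang) * e1 + math.sin(ang) * e2)
        add(name, "C", "TYR", 66, pos)
    # lysine NZ planted relative to the ring
    normal = np.cross(e1, e2)
    normal /= np.linalg.norm(normal)
    if cation_pi is not None:
        L, theta = cation_pi
        direction = math.cos(math.radians(theta)) * normal + math.sin(
            math.radians(theta)
        ) * e1
        nz = ring_center + L * direction
    else:
        nz = ring_center + 12.0 * normal
    add("NZ", "N", "LYS", 55, nz)
    # scaffold filler so the domain is not a pure marker skeleton
    for k, res in enumerate((70, 75, 80, 85)):
        add("CA", "C", "ALA", res, (d / 2.0, -4.0 - 2.5 * k, 0.5 * k))
    return Structure(atoms, label or f"synthetic-sh2-{d:g}A")


def sh2_region_map() -> RegionMap:
    """Region map whose loop definitions match the SH2-like stand-in."""
    return RegionMap(
        {
            "EF_loop": [(CHAIN, 66, 68)],
            "BG_loop": [(CHAIN, 89, 92)],
            "loop_34_40": [(CHAIN, 34, 40)],
            "DE_loop": [(CHAIN, 58, 62)],
        }
    )


# ---------------------------------------------------------------------------
# Trajectory sampling


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic conformer ensemble.

    ``loop_separation_mixture`` is a list of (weight, center A, width A)
    Gaussian components for the EF/BG separation; ``switching_rate``
    optionally replaces independent mixture draws with a two-state
    Markov chain (per-frame transition probability) between the first
    two components. ``cation_pi_fraction`` of frames (exactly, after
    rounding) satisfy the planted (L, theta) contact geometry.
    ``per_residue_amplitude`` is the isotropic per-axis jitter sigma in
    A, scalar or per-residue-number dict.
    """

    n_frames: int = 5400
    dt: float = 0.005
    t0: float = 3.0
    loop_separation_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1.0, 8.8, 0.6)]
    )
    switching_rate: float | None = None
    cation_pi_fraction: float = 0.0
    cation_pi_contact: tuple[float, float] = (5.0, 25.0)
    cation_pi_l_max: float = 8.0
    cation_pi_theta_max: float = 60.0
    per_residue_amplitude: float | dict[int, float] = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        w = np.array([c[0] for c in self.loop_separation_mixture], dtype=float)
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if any(c[2] <= 0 for c in self.loop_separation_mixture):
            raise ValueError("mixture widths must be positive")
        if not 0.0 <= self.cation_pi_fraction <= 1.0:
            raise ValueError("cation_pi_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything that was planted into a sampled trajectory."""

    spec: EnsembleSpec
    loop_separations: np.ndarray
    component_labels: np.ndarray
    cation_pi_flags: np.ndarray

    @property
    def cation_pi_fraction(self) -> float:
        return float(self.cation_pi_flags.mean())

    def to_text(self, path: str | Path) -> None:
        lines = ["# planted ground truth"]
        for i, (w, c, s) in enumerate(self.spec.loop_separation_mixture):
            lines.append(f"mixture_component_{i}: weight={w} center={c} width={s}")
        lines.append(f"cation_pi_fraction: {self.cation_pi_fraction:.6f}")
        lines.append(f"seed: {self.spec.seed}")
        lines.append(f"n_frames: {self.spec.n_frames}")
        lines.append(
            "loop_separations: "
            + " ".join(f"{v:.4f}" for v in self.loop_separations)
        )
        Path(path).write_text("\n".join(lines) + "\n")


def _sample_separations(
    spec: EnsembleSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    comps = spec.loop_separation_mixture
    n = spec.n_frames
    if spec.switching_rate is not None and len(comps) >= 2:
        labels = np.empty(n, dtype=int)
        labels[0] = 0
        flips = rng.random(n - 1) < spec.switching_rate
        for i in range(1, n):
            labels[i] = labels[i - 1] ^ int(flips[i - 1])
    else:
        weights = [c[0] for c in comps]
        labels = rng.choice(len(comps), size=n, p=weights)
    centers = np.array([c[1] for c in comps])
    widths = np.array([c[2] for c in comps])
    values = rng.normal(centers[labels], widths[labels])
    return np.abs(values), labels


def sample_trajectory(spec: EnsembleSpec) -> tuple[Trajectory, GroundTruth]:
    """Sample a synthetic conformer stream with planted observables.

    Per frame: all atoms jitter isotropically with the per-residue
    amplitudes; then the BG marker (Asn92 CA) is placed exactly at the
    sampled loop separation from the EF marker (Gly67 CA) along a fixed
    axis, and the lysine NZ atom is placed exactly at the planted
    cation-pi geometry (contact or non-contact per the deterministic
    planting schedule). Identical seeds give bit-identical trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    template = make_sh2_like_domain(
        loop_separation=spec.loop_separation_mixture[0][1], cation_pi=None
    )
    base = template.coords
    idents = template.identities
    idx_g67 = template.index_of((CHAIN, 67, "CA"))
    idx_n92 = template.index_of((CHAIN, 92, "CA"))
    idx_nz = template.index_of((CHAIN, 55, "NZ"))
    ring_idx = [
        template.index_of((CHAIN, 66, n))
        for n in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ]

    separations, labels = _sample_separations(spec, rng)

    n = spec.n_frames
    n_contact = int(round(spec.cation_pi_fraction * n))
    contact_flags = np.zeros(n, dtype=bool)
    contact_flags[rng.permutation(n)[:n_contact]] = True

    if isinstance(spec.per_residue_amplitude, dict):
        res_sigma = {
            r: float(s) for r, s in spec.per_residue_amplitude.items()
        }
        default_sigma = 0.0
    else:
        res_sigma = {}
        default_sigma = float(spec.per_residue_amplitude)
    res_of_atom = [a.residue_number for a in template.atoms]
    unique_res = sorted(set(res_of_atom))

    # pre-sample the planted cation-pi parameters
    lm, tm = spec.cation_pi_l_max, spec.cation_pi_theta_max
    contact_L = rng.uniform(3.5, max(3.6, lm - 0.5), size=n)
    contact_T = rng.uniform(0.0, max(1.0, tm - 5.0), size=n)
    miss_by_L = rng.random(n) < 0.5
    miss_L = rng.uniform(lm + 1.0, lm + 4.0, size=n)
    miss_T = rng.uniform(min(tm + 5.0, 88.0), 89.0, size=n)

    frames: list[Structure] = []
    for f in range(n):
        coords = base.copy()
        # per-residue isotropic jitter (rigid per residue)
        for res in unique_res:
            sigma = res_sigma.get(res, default_sigma)
            if sigma > 0:
                disp = rng.normal(0.0, sigma, size=3)
                for i, r in enumerate(res_of_atom):
                    if r == res:
                        coords[i] += disp
        # plant the loop separation exactly
        coords[idx_n92] = coords[idx_g67] + separations[f] * LOOP_AXIS
        # plant the cation-pi geometry exactly
        ring = coords[ring_idx]
        centroid = ring.mean(axis=0)
        centered = ring - centroid
        _, evecs = np.linalg.eigh(centered.T @ centered)
        normal = evecs[:, 0]
        in_plane = centered[0] / np.linalg.norm(centered[0])
        if contact_flags[f]:
            L, theta = contact_L[f], contact_T[f]
        elif miss_by_L[f]:
            L, theta = miss_L[f], contact_T[f]
        else:
            L, theta = contact_L[f], miss_T[f]
        direction = (
            math.cos(math.radians(theta)) * normal
            + math.sin(math.radians(theta)) * in_plane
        )
        coords[idx_nz] = centroid + L * direction
        frames.append(
            Structure(
                [
                    Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element,
                        residue_name=a.residue_name,
                        residue_number=a.residue_number,
                        chain=a.chain,
                        position=coords[i],
                        vdw_radius=a.vdw_radius,
                    )
                    for i, a in enumerate(template.atoms)
                ],
                label=f"synthetic-frame-{f + 1}",
            )
        )
    times = spec.t0 + spec.dt * np.arange(n)
    truth = GroundTruth(
        spec=spec,
        loop_separations=separations,
        component_labels=labels,
        cation_pi_flags=contact_flags,
    )
    return Trajectory(frames, times), truth
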