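"""Surface areas against closed-form oracles; groove volume against the
analytic clamp cavity."""

import math

import numpy as np
import pytest

from helpers import random_rotation, random_structure
from shp2md.structure_io import Structure, Trajectory
from shp2md.surface_volume import (
    buried_area,
    groove_volume,
    sphere_surface_area,
    volume_series_average,
)
from shp2md.synthetic import (
    clamp_analytic_volume,
    clamp_region_map,
    make_clamp_structure,
)


def two_sphere_exposed_area(r: float, d: float) -> float:
    """Analytic exposed area per sphere of two equal overlapping spheres:
    4 pi r^2 minus the spherical cap 2 pi r h, h = r - d/2."""
    h = r - d / 2.0
    return 4.0 * math.pi * r**2 - 2.0 * math.pi * r * h


class TestSphereSurfaceArea:
    def test_isolated_sphere_closed_form(self, atom_factory):
        s = Structure([atom_factory(1, radius=1.7)])
        for probe, expected in [(0.0, 4 * math.pi * 1.7**2),
                                (1.4, 4 * math.pi * 3.1**2)]:
            area = sphere_surface_area(s, probe_radius=probe, n_points=960)
            assert area[0] == pytest.approx(expected, rel=5e-3)

    def test_two_sphere_analytic_oracle(self, atom_factory):
        s = Structure([
            atom_factory(1, res=1, pos=(0, 0, 0), radius=1.7),
            atom_factory(2, res=2, pos=(2.0, 0, 0), radius=1.7),
        ])
        areas = sphere_surface_area(s, probe_radius=0.0, n_points=960)
        expected = two_sphere_exposed_area(1.7, 2.0)
        for a in areas:
            assert a == pytest.approx(expected, rel=0.02)

    def test_quadrature_convergence(self):
        frame = random_structure(50, seed=5, box=10.0)
        a960 = np.sum(sphere_surface_area(frame, n_points=960))
        a1920 = np.sum(sphere_surface_area(frame, n_points=1920))
        assert abs(a1920 - a960) / a960 < 0.01

    def test_coincident_centers_rejected(self, atom_factory):
        s = Structure([
            atom_factory(1, res=1, pos=(0, 0, 0)),
            atom_factory(2, res=2, pos=(0, 0, 0)),
        ])
        with pytest.raises(ValueError, match="coincident"):
            sphere_surface_area(s)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_rigid_motion_invariance(self, seed):
        frame = random_structure(20, seed, box=8.0)
        rot = random_rotation(seed + 50)
        moved = frame.with_coords(frame.coords @ rot.T + 11.0)
        a = sphere_surface_area(frame, n_points=960)
        b = sphere_surface_area(moved, n_points=960)
        # invariance up to quadrature noise of the fixed lattice
        assert np.sum(b) == pytest.approx(np.sum(a), rel=2e-3)
        np.testing.assert_allclose(a, b, rtol=0.05, atol=0.1)


class TestBuriedArea:
    def test_identity_holds_by_construction(self):
        frame = random_structure(30, seed=2, box=10.0)
        res = buried_area(frame, {("A", r) for r in range(1, 16)},
                          {("A", r) for r in range(16, 31)})
        assert res.buried == pytest.approx(
            0.5 * (res.a_region_a + res.a_region_b - res.a_complex), abs=1e-9
        )
        assert res.buried > -1e-6
        assert res.a_complex <= res.a_region_a + res.a_region_b + 1e-9

    def test_separated_regions_bury_nothing(self, atom_factory):
        near = [atom_factory(i + 1, res=i + 1, pos=(2.0 * i, 0, 0)) for i in range(3)]
        far = [
            atom_factory(10 + i, res=10 + i, pos=(2.0 * i, 0, 100.0))
            for i in range(3)
        ]
        frame = Structure(near + far)
        res = buried_area(frame, {("A", i + 1) for i in range(3)},
                          {("A", 10 + i) for i in range(3)})
        assert res.buried == pytest.approx(0.0, abs=1e-9)

    def test_two_touching_spheres_bury_the_cap(self, atom_factory):
        frame = Structure([
            atom_factory(1, res=1, pos=(0, 0, 0), radius=1.7),
            atom_factory(2, res=2, pos=(2.0, 0, 0), radius=1.7),
        ])
        res = buried_area(frame, [("A", 1)], [("A", 2)])
        h = 1.7 - 1.0
        assert res.buried == pytest.approx(2 * math.pi * 1.7 * h, rel=0.02)

    def test_constant_docking_gives_flat_series(self, atom_factory):
        """Two domains in fixed contact: the buried-area series stays flat,
        the no-interface-change scenario."""
        atoms_a = [atom_factory(i + 1, res=i + 1, pos=(2.0 * i, 0, 0)) for i in range(4)]
        atoms_b = [atom_factory(10 + i, res=10 + i, pos=(2.0 * i, 2.8, 0)) for i in range(4)]
        frame = Structure(atoms_a + atoms_b)
        rot = random_rotation(9)
        frames = [frame, frame.with_coords(frame.coords @ rot.T + 5.0)]
        values = [
            buried_area(f, {("A", i + 1) for i in range(4)},
                        {("A", 10 + i) for i in range(4)}).buried
            for f in frames
        ]
        assert values[0] > 1.0
        assert values[0] == pytest.approx(values[1], rel=0.05)


class TestGrooveVolume:
    def test_clamp_cavity_matches_analytic_oracle(self):
        for sep in (8.2, 12.0):
            clamp = make_clamp_structure(sep)
            expected = clamp_analytic_volume(sep)
            got = groove_volume(
                clamp, "EF_loop", "BG_loop", grid_spacing=0.4,
                region_map=clamp_region_map(),
            )
            assert got == pytest.approx(expected, rel=0.05)

    def test_volume_strictly_increases_with_mouth_separation(self):
        seps = [6.0, 8.2, 10.0, 11.7, 13.6, 14.8]
        vols = [
            groove_volume(
                make_clamp_structure(s), "EF_loop", "BG_loop",
                grid_spacing=0.5, region_map=clamp_region_map(),
            )
            for s in seps
        ]
        assert all(b > a for a, b in zip(vols, vols[1:]))

    @staticmethod
    def _brute_empty_volume(frame, axis_a, axis_b, radius, spacing):
        """Oracle: empty-cell volume inside the cylindrical envelope with NO
        solvent-connectivity requirement (sealed voids counted)."""
        ca = np.asarray(axis_a, float)
        cb = np.asarray(axis_b, float)
        u = (cb - ca) / np.linalg.norm(cb - ca)
        length = float(np.linalg.norm(cb - ca))
        lo = np.minimum(ca, cb) - radius
        hi = np.maximum(ca, cb) + radius
        grids = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        rel = pts - ca
        t = rel @ u
        rad2 = np.sum(rel * rel, axis=1) - t * t
        inside = (t >= 0) & (t <= length) & (rad2 <= radius**2)
        occupied = np.zeros(len(pts), dtype=bool)
        for atom in frame.atoms:
            if not atom.is_heavy:
                continue
            d2 = np.sum((pts - atom.position) ** 2, axis=1)
            occupied |= d2 < atom.vdw_radius**2
        return float(np.sum(inside & ~occupied)) * spacing**3

    def test_sealed_void_is_excluded(self, atom_factory):
        """A watertight shell of overlapping atoms traps an interior void
        inside the envelope; the flood fill must not count it, while a
        connectivity-blind oracle does."""
        sep = 12.0
        clamp = make_clamp_structure(sep)
        shell = []
        serial = 2000
        spacing, half = 1.2, 3
        for i in range(-half, half + 1):
            for j in range(-half, half + 1):
                for k in range(-half, half + 1):
                    if max(abs(i), abs(j), abs(k)) < half:
                        continue  # hollow interior
                    serial += 1
                    shell.append(
                        atom_factory(
                            serial, name=f"S{serial}", res=500,
                            pos=(i * spacing, j * spacing, sep / 2 + k * spacing),
                        )
                    )
        with_shell = Structure(clamp.atoms + shell)
        axis_a, axis_b = (0.0, 0.0, 0.0), (0.0, 0.0, sep)
        got_plain = groove_volume(clamp, "EF_loop", "BG_loop", grid_spacing=0.5,
                                  region_map=clamp_region_map())
        brute_plain = self._brute_empty_volume(clamp, axis_a, axis_b, 6.0, 0.5)
        # no sealed voids in the bare clamp: flood fill changes nothing
        assert got_plain == pytest.approx(brute_plain, rel=0.02)
        got_shell = groove_volume(with_shell, "EF_loop", "BG_loop", grid_spacing=0.5,
                                  region_map=clamp_region_map())
        brute_shell = self._brute_empty_volume(with_shell, axis_a, axis_b, 6.0, 0.5)
        # the sealed interior (tens of A^3) is counted by the oracle only
        assert brute_shell - got_shell > 30.0

    @pytest.mark.parametrize("seed", [4])
    def test_rigid_motion_invariance(self, seed):
        clamp = make_clamp_structure(9.0)
        rot = random_rotation(seed)
        moved = clamp.with_coords(clamp.coords @ rot.T + 7.0)
        v1 = groove_volume(clamp, "EF_loop", "BG_loop", grid_spacing=0.5,
                           region_map=clamp_region_map())
        v2 = groove_volume(moved, "EF_loop", "BG_loop", grid_spacing=0.5,
                           region_map=clamp_region_map())
        assert v2 == pytest.approx(v1, rel=0.03)

    def test_coincident_mouths_rejected(self, atom_factory):
        atoms = [
            atom_factory(1, name="CA", res=67, pos=(0, 0, 0)),
            atom_factory(2, name="CA", res=92, pos=(0, 0, 0)),
        ]
        with pytest.raises(Exception):
            groove_volume(
                Structure(atoms), [("A", 67)], [("A", 92)], grid_spacing=0.5
            )


class TestVolumeSeriesAverage:
    def test_constant_geometry_has_zero_sd(self):
        clamp = make_clamp_structure(9.0)
        traj = Trajectory([clamp] * 4, [0, 1, 2, 3])
        vs = volume_series_average(
            traj, window=(0.0, 3.0), stride_ns=1.0,
            mouth_a="EF_loop", mouth_b="BG_loop",
            grid_spacing=0.5, region_map=clamp_region_map(),
        )
        assert vs.sd == pytest.approx(0.0, abs=1e-12)
        assert len(vs.volumes) == 4

    def test_alternating_geometries_average_to_midpoint(self):
        a = make_clamp_structure(8.2)
        b = a.with_coords(make_clamp_structure(12.0).coords)
        traj = Trajectory([a, b, a, b], [0, 1, 2, 3])
        vs = volume_series_average(
            traj, window=(0.0, 3.0), stride_ns=1.0,
            mouth_a="EF_loop", mouth_b="BG_loop",
            grid_spacing=0.5, region_map=clamp_region_map(),
        )
        va = groove_volume(a, "EF_loop", "BG_loop", grid_spacing=0.5,
                           region_map=clamp_region_map())
        vb = groove_volume(b, "EF_loop", "BG_loop", grid_spacing=0.5,
                           region_map=clamp_region_map())
        assert vs.mean == pytest.approx((va + vb) / 2.0, rel=1e-9)

    def test_window_outside_trajectory_errors(self):
        clamp = make_clamp_structure(9.0)
        traj = Trajectory([clamp, clamp], [0.0, 1.0])
        with pytest.raises(ValueError, match="window"):
            volume_series_average(
                traj, window=(3.0, 30.0), mouth_a="EF_loop", mouth_b="BG_loop",
                region_map=clamp_region_map(),
            )
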