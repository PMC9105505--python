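"""Fraction curves, joint Gaussian deconvolution, cation-pi geometry,
averaged conformers, and the hypergeometric outcome probability."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from helpers import make_atom, random_rotation
from shp2md.ensemble_stats import (
    FractionCurve,
    average_conformer,
    cation_pi_fraction,
    cation_pi_geometry,
    fit_column,
    fraction_curve,
    hypergeometric_outcome_p,
)
from shp2md.geometry import DistanceSeries, distance_series
from shp2md.structure_io import Structure, Trajectory
from shp2md.synthetic import EnsembleSpec, make_sh2_like_domain, sample_trajectory


def _series(values, times=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return DistanceSeries("toy", times, values, (("A", 1, "CA"), ("A", 2, "CA")))


class TestFractionCurve:
    def test_point_mass(self):
        curve = fraction_curve(_series([8.0] * 10), window_width=1.5, step=1.5)
        assert curve.fractions.max() == pytest.approx(1.0)
        assert curve.fractions.sum() == pytest.approx(1.0)

    def test_two_equal_peaks(self):
        curve = fraction_curve(
            _series([8.0] * 50 + [14.0] * 50), window_width=1.5, step=1.5
        )
        peaks = sorted(curve.fractions[curve.fractions > 0])
        assert peaks == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_disjoint_tiling_sums_to_one_exactly(self):
        rng = np.random.default_rng(0)
        curve = fraction_curve(
            _series(rng.normal(10, 2, size=1000)), window_width=1.5, step=1.5
        )
        assert curve.fractions.sum() == 1.0

    def test_gaussian_series_matches_binomial_oracle(self):
        """For N(10, 0.5^2) samples, each window's count is Binomial(n, p)
        with p the analytic Gaussian mass in the window; every observed
        fraction must fall within 3 binomial sigmas."""
        rng = np.random.default_rng(42)
        n = 5400
        vals = rng.normal(10.0, 0.5, size=n)
        w = 1.5
        curve = fraction_curve(_series(vals), window_width=w, step=w)
        for c, f in zip(curve.window_centers, curve.fractions):
            p = norm.cdf(c + w / 2, 10.0, 0.5) - norm.cdf(c - w / 2, 10.0, 0.5)
            sigma = math.sqrt(max(p * (1 - p) / n, 1e-12))
            assert abs(f - p) <= 3.0 * sigma + 1e-9

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fraction_curve(np.array([]), window_width=1.5, step=1.5)


class TestFitColumn:
    def _gaussian_curve(self, x, centers, widths, amps):
        y = np.zeros_like(x)
        for c, w, a in zip(centers, widths, amps):
            y += a * np.exp(-((x - c) ** 2) / (2 * w**2))
        return y

    def test_exact_single_gaussian_recovered(self):
        x = np.arange(5.0, 12.0, 0.25)
        y = self._gaussian_curve(x, [8.5], [0.6], [0.3])
        fit = fit_column([FractionCurve(x, y, 1.5, "exact")], 1, seed=0)
        assert fit.centers[0] == pytest.approx(8.5, abs=1e-3)
        assert fit.widths[0] == pytest.approx(0.6, abs=1e-3)
        assert fit.amplitudes[0, 0] == pytest.approx(0.3, abs=1e-3)
        assert fit.residual < 1e-8

    def test_three_curves_shared_parameters_with_noise(self):
        """Three constructs sharing component centers/widths but with
        distinct populations: the joint fit recovers the shared parameters
        and the per-curve amplitudes."""
        x = np.arange(6.0, 17.0, 0.3)
        centers, widths = [8.8, 13.6], [0.7, 0.9]
        amp_vectors = [(0.30, 0.02), (0.18, 0.15), (0.03, 0.28)]
        rng = np.random.default_rng(5)
        curves = []
        for i, amps in enumerate(amp_vectors):
            y = self._gaussian_curve(x, centers, widths, amps)
            y = np.clip(y * (1 + rng.normal(0, 0.01, size=y.shape)), 0, 1)
            curves.append(FractionCurve(x, y, 1.5, f"c{i}"))
        fit = fit_column(curves, 2, seed=1)
        np.testing.assert_allclose(fit.centers, centers, atol=0.1)
        np.testing.assert_allclose(fit.widths, widths, atol=0.1)
        for i, amps in enumerate(amp_vectors):
            np.testing.assert_allclose(
                fit.amplitudes[i], amps, rtol=0.05, atol=0.01
            )

    def test_residual_non_increasing_in_k(self):
        x = np.arange(6.0, 17.0, 0.3)
        y = self._gaussian_curve(x, [8.8, 13.6], [0.7, 0.9], [0.3, 0.2])
        curves = [FractionCurve(x, y, 1.5, "c")]
        r1 = fit_column(curves, 1, seed=0).residual
        r2 = fit_column(curves, 2, seed=0).residual
        assert r2 <= r1 + 1e-12

    def test_curve_order_permutation_gives_same_shared_parameters(self):
        x = np.arange(6.0, 17.0, 0.3)
        curves = [
            FractionCurve(
                x,
                self._gaussian_curve(x, [8.8, 13.6], [0.7, 0.9], amps),
                1.5,
                f"c{i}",
            )
            for i, amps in enumerate([(0.3, 0.05), (0.1, 0.25)])
        ]
        fit_ab = fit_column(curves, 2, seed=3)
        fit_ba = fit_column(curves[::-1], 2, seed=3)
        np.testing.assert_allclose(fit_ab.centers, fit_ba.centers, atol=1e-4)
        np.testing.assert_allclose(fit_ab.widths, fit_ba.widths, atol=1e-4)
        np.testing.assert_allclose(
            fit_ab.amplitudes, fit_ba.amplitudes[::-1], atol=1e-4
        )

    def test_k_exceeding_windows_rejected(self):
        x = np.arange(3)
        with pytest.raises(ValueError, match="exceeds"):
            fit_column([FractionCurve(x, np.zeros(3), 1.5)], 5)

    def test_sampled_mixture_centers_recovered(self):
        """End-to-end: frames sampled from a two-component separation
        mixture; the fitted shared centers land within 0.15 A."""
        spec = EnsembleSpec(
            n_frames=5400,
            loop_separation_mixture=[(0.5, 8.8, 0.6), (0.5, 13.6, 0.8)],
            seed=11,
        )
        traj, truth = sample_trajectory(spec)
        d = distance_series(traj, (("A", 67, "CA"), ("A", 92, "CA")))
        curve = fraction_curve(d, window_width=1.5, step=0.3)
        fit = fit_column([curve], 2, seed=2)
        np.testing.assert_allclose(fit.centers, [8.8, 13.6], atol=0.15)


class TestCationPi:
    def _ring(self, center=(0.0, 0.0, 0.0)):
        """Regular hexagon of radius 1.39 in the xy plane."""
        center = np.asarray(center, float)
        return np.array(
            [
                center
                + 1.39 * np.array([math.cos(math.radians(60 * k)),
                                   math.sin(math.radians(60 * k)), 0.0])
                for k in range(6)
            ]
        )

    def test_charge_on_normal_is_contact(self):
        geom = cation_pi_geometry(np.array([0.0, 0, 6.0]), self._ring())
        assert geom.L == pytest.approx(6.0)
        assert geom.theta == pytest.approx(0.0, abs=1e-9)

    def test_charge_in_plane_is_not_contact(self):
        geom = cation_pi_geometry(np.array([6.0, 0, 0.0]), self._ring())
        assert geom.theta == pytest.approx(90.0, abs=1e-9)

    def test_normal_sign_folding(self):
        below = cation_pi_geometry(np.array([0.0, 0, -6.0]), self._ring())
        assert below.theta == pytest.approx(0.0, abs=1e-9)

    def test_theta_invariant_under_in_plane_ring_rotation(self):
        nz = np.array([2.0, 1.0, 5.0])
        base = cation_pi_geometry(nz, self._ring())
        ring = self._ring()
        ang = math.radians(37.0)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang), 0],
             [math.sin(ang), math.cos(ang), 0],
             [0, 0, 1]]
        )
        rotated = ring @ rot.T
        assert cation_pi_geometry(nz, rotated).theta == pytest.approx(
            base.theta, abs=1e-9
        )

    def test_invariant_under_global_rigid_motion(self):
        nz = np.array([1.0, 2.0, 5.0])
        ring = self._ring()
        rot = random_rotation(3)
        shift = np.array([4.0, -2.0, 9.0])
        a = cation_pi_geometry(nz, ring)
        b = cation_pi_geometry(nz @ rot.T + shift, ring @ rot.T + shift)
        assert b.L == pytest.approx(a.L, abs=1e-9)
        assert b.theta == pytest.approx(a.theta, abs=1e-9)

    @pytest.mark.parametrize(
        "theta,counted", [(59.9, True), (60.1, False)]
    )
    def test_theta_boundary_at_sixty_degrees(self, theta, counted):
        """L = 6 A planted exactly; only theta decides the contact."""
        frames = [
            make_sh2_like_domain(8.2, cation_pi=(6.0, theta)) for _ in range(2)
        ]
        traj = Trajectory(frames, [0.0, 1.0])
        frac = cation_pi_fraction(
            traj, ("A", 55), ("A", 66), l_max=8.0, theta_max=60.0, window=None
        )
        assert frac == (1.0 if counted else 0.0)

    def test_planted_fraction_recovered_exactly(self):
        spec = EnsembleSpec(n_frames=500, cation_pi_fraction=0.40, seed=3)
        traj, truth = sample_trajectory(spec)
        frac = cation_pi_fraction(traj, ("A", 55), ("A", 66), window=None)
        assert frac == truth.cation_pi_fraction == 0.40

    def test_missing_ring_atoms_reported(self):
        atoms = [
            make_atom(1, name="NZ", element="N", res=55, pos=(0, 0, 0)),
            make_atom(2, name="CA", res=66, pos=(3, 0, 0)),
            make_atom(3, name="CA", res=55, pos=(1, 0, 0)),
        ]
        traj = Trajectory([Structure(atoms)] * 2, [0, 1])
        with pytest.raises(KeyError, match="ring"):
            cation_pi_fraction(traj, ("A", 55), ("A", 66), window=None)


class TestAverageConformer:
    def test_identical_frames_average_to_themselves(self):
        s = make_sh2_like_domain(8.2)
        traj = Trajectory([s, s, s], [0, 1, 2])
        avg = average_conformer(traj, align_selection="ca")
        np.testing.assert_allclose(avg.coords, s.coords, atol=1e-9)
        assert all(a.bfactor == pytest.approx(0.0, abs=1e-9) for a in avg)

    def test_symmetric_displacement_gives_half_amplitude_rmsd(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(-8, 8, (10, 3))
        up, down = coords.copy(), coords.copy()
        up[4, 2] += 0.5
        down[4, 2] -= 0.5
        frames = [
            Structure(
                [make_atom(i + 1, res=i + 1, pos=c[i]) for i in range(10)]
            )
            for c in (up, down)
        ]
        traj = Trajectory(frames, [0, 1])
        align = [("A", r + 1, "CA") for r in range(10) if r != 4]
        avg = average_conformer(traj, align_selection=align)
        bf = {a.residue_number: a.bfactor for a in avg}
        assert bf[5] == pytest.approx(0.5, abs=1e-9)
        for r, v in bf.items():
            if r != 5:
                assert v == pytest.approx(0.0, abs=1e-9)

    def test_planted_fluctuation_amplitudes_recovered(self):
        """Isotropic per-residue jitter sigma implies CA RMSD about the mean
        of sigma * sqrt(3); the annotation recovers it within sampling
        error (the anchor residue carries no jitter by construction)."""
        amp = {36: 0.3, 38: 0.05}
        spec = EnsembleSpec(
            n_frames=400,
            per_residue_amplitude=amp,
            loop_separation_mixture=[(1.0, 8.8, 1e-6)],
            seed=21,
        )
        traj, _ = sample_trajectory(spec)
        avg = average_conformer(traj, align_selection=[("A", 70, "CA"),
                                                       ("A", 75, "CA"),
                                                       ("A", 80, "CA"),
                                                       ("A", 85, "CA")])
        bf = {a.residue_number: a.bfactor for a in avg if a.name == "CA"}
        assert bf[36] == pytest.approx(0.3 * math.sqrt(3), rel=0.15)
        assert bf[38] == pytest.approx(0.05 * math.sqrt(3), rel=0.2)


class TestHypergeometricOutcome:
    def test_perfect_split_of_six_runs(self):
        assert hypergeometric_outcome_p(6, 3, 3) == pytest.approx(0.05)

    def test_two_items_one_group(self):
        assert hypergeometric_outcome_p(2, 1, 1) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", range(2, 11))
    def test_matches_enumeration_oracle(self, n):
        """Exhaustive oracle: over all C(n, k) group choices, the fraction
        with exactly j of the k outcome-carriers inside the group."""
        for k in range(1, n + 1):
            carriers = set(range(k))
            total = 0
            by_j = {}
            for group in itertools.combinations(range(n), k):
                j = len(carriers & set(group))
                by_j[j] = by_j.get(j, 0) + 1
                total += 1
            for j in range(0, k + 1):
                expected = by_j.get(j, 0) / total
                assert hypergeometric_outcome_p(n, k, j) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_tail_option_upper_tail(self):
        # P(X >= 2) with n=6, group=3: (9 + 1) / 20
        assert hypergeometric_outcome_p(6, 3, 2, tail=True) == pytest.approx(0.5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_outcome_p(6, 3, 4)
        with pytest.raises(ValueError):
            hypergeometric_outcome_p(3, 6, 1)
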