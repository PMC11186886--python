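"""Morphometrics: axis recovery, per-strand twist, crossover arithmetic,
RMSD, zipper distance distributions and the N-to-C g(r)."""

import numpy as np
import pytest

from conftest import make_ca_trajectory
from crossbeta.builder import ScrewParameters, build_fibril
from crossbeta.geometry import rotation_about_axis
from crossbeta.synthetic import SyntheticSpec, make_fibril_trajectory
from crossbeta.twist import (
    crossover,
    curvature,
    fibril_axis,
    interface_distance_distribution,
    nter_cter_gofr,
    per_strand_twist,
    rmsd_ca,
    twist_time_series,
)


class TestFibrilAxis:
    def test_builder_output_axis_is_z(self, small_model):
        axis, _ = fibril_axis(small_model.atoms, small_model.topology)
        assert abs(np.dot(axis, [0, 0, 1])) > 1 - 1e-6
        assert axis[2] > 0  # oriented toward increasing strand index

    def test_equivariance_under_rotation(self, small_model):
        R = rotation_about_axis([1, 1, 0], 63.0)
        rotated = small_model.atoms.copy()
        rotated.coord = small_model.atoms.coord @ R.T
        axis0, _ = fibril_axis(small_model.atoms, small_model.topology)
        axis1, _ = fibril_axis(rotated, small_model.topology)
        assert np.allclose(axis1, R @ axis0, atol=1e-6)

    def test_recovery_under_noise(self):
        spec = SyntheticSpec(
            n_strands=10, twist=2.0, noise_sigma=0.5, n_frames=1, seed=2,
            full_length=False,
        )
        traj = make_fibril_trajectory(spec)
        axis, _ = fibril_axis(traj.frame(0), traj.topology)
        angle = np.degrees(np.arccos(abs(np.clip(axis[2], -1, 1))))
        assert angle < 1.0


class TestPerStrandTwist:
    def test_planted_twist_recovered_noise_free(self):
        for planted in (0.0, 1.8, 2.2):
            model = build_fibril(
                "human", n_per_layer=5, screw=ScrewParameters(twist=planted),
                full_length=False, box_margin=10,
            )
            prof = per_strand_twist(model.atoms, model.topology)
            assert abs(prof.mean_twist - planted) < 1e-3
            assert abs(prof.rise_estimate - 4.8) < 1e-3
            assert np.isclose(prof.mean_twist, prof.per_pair_angles.mean())

    def test_invariance_under_rigid_motion(self, small_model):
        prof0 = per_strand_twist(small_model.atoms, small_model.topology)
        R = rotation_about_axis([2, -1, 5], 119.0)
        moved = small_model.atoms.copy()
        moved.coord = small_model.atoms.coord @ R.T + np.array([10.0, -4.0, 2.0])
        prof1 = per_strand_twist(moved, small_model.topology)
        assert abs(prof1.mean_twist - prof0.mean_twist) < 1e-4


class TestCrossover:
    @pytest.mark.parametrize(
        "twist, rise, strands, distance",
        [
            (2.2, 4.8, 82, 39.36),  # the 36-mer's equilibrated morphology
            (1.8, 4.8, 100, 48.0),
            (180.0, 4.8, 1, 0.48),
        ],
    )
    def test_reference_values(self, twist, rise, strands, distance):
        n, d = crossover(twist, rise)
        assert n == strands
        assert np.isclose(d, distance, atol=1e-9)

    def test_inverse_consistency(self):
        """crossover(180/n) = (n, n·rise/10) exactly for integer n."""
        for n in (1, 7, 82, 94, 100):
            strands, dist = crossover(180.0 / n, 4.8)
            assert strands == n
            assert np.isclose(dist, n * 0.48)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            crossover(0.0)
        with pytest.raises(ValueError):
            crossover(2.0, rise=-1.0)


class TestRmsd:
    def test_self_is_zero(self, small_model):
        assert rmsd_ca(small_model.atoms, small_model.atoms) == 0.0

    def test_translation(self, small_model):
        moved = small_model.atoms.copy()
        moved.coord = small_model.atoms.coord + np.array([3.0, 4.0, 0.0])
        # coordinates are stored float32, limiting exact recovery to ~1e-5 Å
        assert rmsd_ca(moved, small_model.atoms, superpose=True) < 1e-5
        assert np.isclose(rmsd_ca(moved, small_model.atoms, superpose=False), 5.0, atol=1e-5)

    def test_random_rotation_recovered(self, small_model):
        R = rotation_about_axis([0.3, 1, 2], 147.0)
        moved = small_model.atoms.copy()
        moved.coord = small_model.atoms.coord @ R.T
        assert rmsd_ca(moved, small_model.atoms, superpose=True) < 1e-4

    def test_superposed_never_larger(self, small_model):
        rng = np.random.default_rng(8)
        noisy = small_model.atoms.copy()
        noisy.coord = small_model.atoms.coord + rng.normal(0, 1.0, small_model.atoms.coord.shape)
        with_sp = rmsd_ca(noisy, small_model.atoms, superpose=True)
        without = rmsd_ca(noisy, small_model.atoms, superpose=False)
        assert with_sp <= without + 1e-12


class TestDistanceDistributions:
    def test_static_delta_distribution(self):
        traj = make_ca_trajectory(np.full((3, 4), 10.0))
        dist = interface_distance_distribution(traj, [(1, 42)], bin_width=1.0)
        assert dist.density.max() == 1.0  # a delta: all mass in one bin
        assert abs(dist.mode - 10.0) <= 0.5
        assert np.isclose(dist.density.sum(), 1.0)

    def test_bimodal_modes_recovered(self):
        rng = np.random.default_rng(5)
        n = 400
        samples = np.concatenate(
            [rng.normal(8.0, 0.4, n), rng.normal(12.0, 0.4, n)]
        )
        traj = make_ca_trajectory(samples.reshape(-1, 1))
        dist = interface_distance_distribution(traj, [(1, 42)], bin_width=0.5)
        centres = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        peaks = centres[np.argsort(dist.density)[-4:]]
        assert np.any(np.abs(peaks - 8.0) < 0.5)
        assert np.any(np.abs(peaks - 12.0) < 0.5)

    def test_width_grows_with_sigma(self):
        rng = np.random.default_rng(6)
        widths = []
        for sigma in (0.2, 0.6, 1.2, 2.0):
            samples = rng.normal(10.0, sigma, 2000).clip(min=0.5)
            traj = make_ca_trajectory(samples.reshape(-1, 1))
            dist = interface_distance_distribution(traj, [(1, 42)], bin_width=0.25)
            centres = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
            mean = (centres * dist.density).sum()
            widths.append(np.sqrt(((centres - mean) ** 2 * dist.density).sum()))
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_empty_pairs_rejected(self, small_model):
        traj = make_ca_trajectory([[10.0]])
        with pytest.raises(ValueError):
            interface_distance_distribution(traj, [])


class TestNterCterGofr:
    def test_frozen_distance_mode(self):
        traj = make_ca_trajectory(np.full((5, 3), 30.0))
        dist = nter_cter_gofr(traj)
        assert abs(dist.mode - 30.0) <= 0.5
        assert np.isclose(dist.density.sum(), 1.0)

    def test_planted_ensembles(self):
        rng = np.random.default_rng(9)
        extended = make_ca_trajectory(rng.normal(43.0, 2.0, (300, 6)))
        folded = make_ca_trajectory(rng.normal(30.0, 2.0, (300, 6)))
        assert abs(nter_cter_gofr(extended).mode - 43.0) <= 1.0
        assert abs(nter_cter_gofr(folded).mode - 30.0) <= 1.0


def test_twist_time_series_and_curvature(small_model):
    spec = SyntheticSpec(
        n_strands=5, twist=2.2, noise_sigma=0.0, n_frames=3, seed=1, full_length=False
    )
    traj = make_fibril_trajectory(spec)
    frames, means = twist_time_series(traj)
    assert len(means) == 3
    assert np.allclose(means, 2.2, atol=1e-3)
    # noise-free straight fibril has (numerically) no arching
    assert curvature(traj.frame(0), traj.topology) < 0.5
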