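"""Superposition, RMSF, order parameter and radius of gyration."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fibrilkit import (
    GeneratorParams,
    PlantedMode,
    compute_ordp,
    compute_rmsf,
    generate_trajectory,
    kabsch_superpose,
    ordp_distribution,
    radius_of_gyration,
    sinusoid_amplitudes,
)
from fibrilkit.core import AssemblyFrame, StructureError, Trajectory
from fibrilkit.geometry import OrdPSeries
from fibrilkit.synthetic import make_cterminal_mode

from conftest import make_toy_topology


def _toy_frame(coords, elements=None):
    n = len(coords)
    top = make_toy_topology(
        atom_names=["CA"] * n,
        elements=["C"] * n if elements is None else elements,
        residue_numbers=list(range(1, n + 1)),
        chain_ids=["A"] * n,
    )
    return AssemblyFrame(top, np.asarray(coords, dtype=float))


class TestKabsch:
    def test_self_superposition_rmsd_zero(self, ideal_u):
        frame = ideal_u.frame(0)
        _, rmsd = kabsch_superpose(frame, frame)
        assert rmsd <= 1e-12

    def test_rigid_copy_recovered(self, ideal_u):
        frame = ideal_u.frame(0)
        rot = Rotation.from_euler("zyx", [40.0, -25.0, 110.0], degrees=True).as_matrix()
        moved = AssemblyFrame(
            frame.topology, frame.coordinates @ rot.T + np.array([1.0, -2.0, 0.5])
        )
        _, rmsd = kabsch_superpose(moved, frame)
        assert rmsd <= 1e-6

    def test_matches_rotation_search_oracle_on_toy(self):
        """Kabsch RMSD equals a grid+refine search over all rotations."""
        rng = np.random.default_rng(4)
        a = _toy_frame(rng.normal(size=(4, 3)) * 0.2)
        b_coords = a.coordinates + rng.normal(size=(4, 3)) * 0.05
        b = _toy_frame(b_coords)
        _, rmsd = kabsch_superpose(a, b)

        ac = a.coordinates - a.coordinates.mean(axis=0)
        bc = b.coordinates - b.coordinates.mean(axis=0)

        def cost(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1)))

        # coarse deterministic quaternion grid, then local refinement
        best = None
        for q in Rotation.random(2000, random_state=0).as_rotvec():
            c = cost(q)
            if best is None or c < best[0]:
                best = (c, q)
        refined = minimize(cost, best[1], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        assert abs(rmsd - refined.fun) <= 1e-4

    def test_collinear_selection_is_diagnosed(self):
        line = _toy_frame(np.outer(np.arange(4.0), [1.0, 0.0, 0.0]))
        with pytest.raises(StructureError, match="degenerate"):
            kabsch_superpose(line, line)


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self, ideal_u):
        prof = compute_rmsf(ideal_u)
        assert np.all(prof.mean == 0.0)
        assert np.all(prof.std == 0.0)

    def test_single_frame_is_an_error(self, ideal_u):
        single = Trajectory(ideal_u.topology, ideal_u.coordinates[:1])
        with pytest.raises(StructureError, match="RMSF"):
            compute_rmsf(single)

    def test_rigid_body_motion_does_not_contribute(self, noisy_u):
        """Composing a per-frame rigid motion changes nothing after fitting."""
        base = compute_rmsf(noisy_u)
        rng = np.random.default_rng(0)
        coords = noisy_u.coordinates.copy()
        for f in range(1, coords.shape[0]):
            rot = Rotation.from_rotvec(rng.normal(size=3) * 0.3).as_matrix()
            coords[f] = coords[f] @ rot.T + rng.normal(size=3)
        moved = Trajectory(noisy_u.topology, coords)
        prof = compute_rmsf(moved)
        assert np.allclose(prof.mean, base.mean, atol=1e-9)

    def test_planted_mode_peaks_at_its_residues(self):
        planted = make_cterminal_mode(5)
        traj = generate_trajectory(
            GeneratorParams(
                shape="U",
                n_frames=300,
                noise_sigma=0.005,
                planted_mode=PlantedMode(
                    directions=planted,
                    amplitudes=sinusoid_amplitudes(300, 0.2, seed=2),
                ),
                seed=2,
            )
        )
        prof = compute_rmsf(traj, atoms="calpha")
        # chain E (index 4) carries the mode on residues 36-42
        carried = prof.per_chain[4][prof.residue_numbers >= 36].mean()
        baseline = prof.per_chain[4][prof.residue_numbers < 36].mean()
        assert carried > 5 * baseline


class TestOrdP:
    def test_ideal_pentamer_is_exactly_one(self, ideal_u):
        assert np.all(compute_ordp(ideal_u).values == 1.0)

    def test_uniform_60_degree_tilt_gives_half(self):
        traj = generate_trajectory(GeneratorParams(n_frames=2, stack_tilt=60.0))
        assert np.abs(compute_ordp(traj).values - 0.5).max() <= 1e-10

    def test_isotropic_stacking_has_zero_mean(self):
        """i.i.d. uniform cross-fibril directions → mean ordP → 0."""
        n_res, n_frames = 400, 50
        rng = np.random.default_rng(8)
        top = make_toy_topology(
            atom_names=["CA"] * (2 * n_res),
            elements=["C"] * (2 * n_res),
            residue_numbers=list(range(1, n_res + 1)) * 2,
            chain_ids=["A"] * n_res + ["B"] * n_res,
            chain_order=("A", "B"),
        )
        coords = np.empty((n_frames, 2 * n_res, 3))
        for f in range(n_frames):
            a = rng.normal(size=(n_res, 3)) * 5.0
            v = rng.normal(size=(n_res, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            coords[f, :n_res] = a
            coords[f, n_res:] = a + v
        series = compute_ordp(Trajectory(top, coords))
        assert abs(series.values.mean()) < 3.0 / np.sqrt(n_res * n_frames)

    def test_translation_and_fitted_rotation_invariance(self, noisy_u):
        base = compute_ordp(noisy_u).values
        shifted = Trajectory(noisy_u.topology, noisy_u.coordinates + np.array([3.0, -1.0, 2.0]))
        assert np.allclose(compute_ordp(shifted).values, base, atol=1e-9)
        rot = Rotation.from_euler("xyz", [30, 45, -60], degrees=True).as_matrix()
        coords = noisy_u.coordinates.copy()
        coords[1:] = coords[1:] @ rot.T  # reference frame untouched
        rotated = Trajectory(noisy_u.topology, coords)
        assert np.allclose(compute_ordp(rotated).values, base, atol=1e-9)

    def test_values_bounded_and_per_frame_convention(self, noisy_u):
        for convention in ("reference-fit", "per-frame"):
            s = compute_ordp(noisy_u, convention=convention)
            assert np.all(np.abs(s.values) <= 1.0)


class TestOrdPDistribution:
    def test_constant_series_single_bin_integrates_to_one(self):
        s = OrdPSeries(values=np.full(50, 0.75), convention="reference-fit", endpoints=("A", "E"))
        centers, density = ordp_distribution(s, 20)
        width = centers[1] - centers[0]
        assert np.isclose((density * width).sum(), 1.0)
        assert np.count_nonzero(density) == 1

    def test_two_valued_series_has_equal_mass(self):
        vals = np.array([0.25, -0.25] * 30)
        s = OrdPSeries(values=vals, convention="reference-fit", endpoints=("A", "E"))
        centers, density = ordp_distribution(s, 8)
        occupied = density[density > 0]
        assert len(occupied) == 2
        assert np.isclose(occupied[0], occupied[1])

    def test_bin_centre_values_reproduce_the_mean(self):
        centers_ref = np.linspace(-1, 1, 11)[:-1] + 0.1
        vals = np.repeat(centers_ref[[2, 7]], 25)
        s = OrdPSeries(values=vals, convention="reference-fit", endpoints=("A", "E"))
        centers, density = ordp_distribution(s, 10)
        width = centers[1] - centers[0]
        hist_mean = (centers * density * width).sum()
        assert abs(hist_mean - vals.mean()) <= 1e-12

    def test_too_few_bins_rejected(self):
        s = OrdPSeries(values=np.zeros(3), convention="reference-fit", endpoints=("A", "E"))
        with pytest.raises(ValueError):
            ordp_distribution(s, 1)


class TestRadiusOfGyration:
    def test_two_unit_mass_atoms(self):
        frame = _toy_frame([[0.0, 0.0, 0.0], [0.2, 0.0, 0.0]])
        assert np.isclose(radius_of_gyration(frame, masses=np.ones(2)), 0.1)

    def test_coincident_atoms_give_zero(self):
        frame = _toy_frame(np.zeros((5, 3)))
        assert radius_of_gyration(frame) == 0.0

    def test_matches_direct_sum_oracle_and_scales_linearly(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(100, 3))
        frame = _toy_frame(coords)
        rg = radius_of_gyration(frame, masses=np.ones(100))
        com = coords.mean(axis=0)
        oracle = np.sqrt(sum(np.sum((c - com) ** 2) for c in coords) / 100)
        assert abs(rg - oracle) <= 1e-12
        doubled = _toy_frame(coords * 2.0)
        assert np.isclose(radius_of_gyration(doubled, masses=np.ones(100)), 2 * rg)

    def test_empty_selection_rejected(self, ideal_u):
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(ideal_u.frame(0), selection=np.array([], dtype=int))
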