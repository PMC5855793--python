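"""Contact/H-bond maps against brute-force oracles; dihedral classifier."""

import numpy as np
import pytest

from fibrilkit import (
    GeneratorParams,
    Trajectory,
    classify_secondary_structure,
    generate_trajectory,
    hydrogen_bond_map,
    interchain_contact_profile,
    nonbonded_contact_map,
)
from fibrilkit.synthetic import build_ideal_chain

from conftest import make_toy_topology


# ----------------------------------------------------------------------
# Brute-force O(N²) oracles (no neighbour lists, no blocking)
# ----------------------------------------------------------------------

def brute_contact_profile(traj, chain_pairs, cutoff):
    top = traj.topology
    res = top.residue_numbers
    counts = np.zeros(len(res))
    n_obs = 0
    for x, y in chain_pairs:
        for f in range(traj.n_frames):
            c = traj.coordinates[f]
            for first, second in ((x, y), (y, x)):
                for ri, r in enumerate(res):
                    sel_r = np.flatnonzero(
                        top.residue_mask(first, r) & top.heavy_mask
                    )
                    sel_other = np.flatnonzero(top.chain_mask(second) & top.heavy_mask)
                    dmin = min(
                        np.linalg.norm(c[i] - c[j])
                        for i in sel_r
                        for j in sel_other
                    )
                    counts[ri] += dmin <= cutoff
                n_obs += 1
    return counts / n_obs


def brute_nonbonded_map(traj, chain_pairs, cutoff):
    top = traj.topology
    res = top.residue_numbers
    counts = np.zeros((len(res), len(res)))
    n_obs = 0
    for x, y in chain_pairs:
        for f in range(traj.n_frames):
            c = traj.coordinates[f]
            hit = np.zeros_like(counts, dtype=bool)
            for i, ri in enumerate(res):
                for j, rj in enumerate(res):
                    a = np.flatnonzero(top.residue_mask(x, ri) & top.heavy_mask)
                    b = np.flatnonzero(top.residue_mask(y, rj) & top.heavy_mask)
                    dmin = min(
                        np.linalg.norm(c[p] - c[q]) for p in a for q in b
                    )
                    hit[i, j] = dmin <= cutoff
            counts += hit
            counts += hit.T
            n_obs += 2
    return counts / n_obs


def brute_hbond_map_inter(traj, chain_pairs, cutoff):
    """Distance-only donor(N)→acceptor(O) probability, either direction."""
    top = traj.topology
    res = top.residue_numbers
    counts = np.zeros((len(res), len(res)))
    n_obs = 0
    for x, y in chain_pairs:
        for f in range(traj.n_frames):
            c = traj.coordinates[f]
            for i, ri in enumerate(res):
                for j, rj in enumerate(res):
                    found = False
                    for donor_chain, acc_chain in ((x, y), (y, x)):
                        dn = np.flatnonzero(
                            top.residue_mask(donor_chain, ri) & (top.element == "N")
                        )
                        ac = np.flatnonzero(
                            top.residue_mask(acc_chain, rj) & (top.element == "O")
                        )
                        for p in dn:
                            for q in ac:
                                if np.linalg.norm(c[p] - c[q]) <= cutoff:
                                    found = True
                    counts[i, j] += found
            n_obs += 1
    return counts / n_obs


@pytest.fixture(scope="module")
def small_noisy():
    """Small disordered fixture (≤1000 atoms) for exact oracle comparison."""
    traj = generate_trajectory(
        GeneratorParams(shape="U", n_chains=3, n_frames=2, noise_sigma=0.15, seed=17)
    )
    return traj


class TestOracleEquivalence:
    def test_contact_profile_equals_brute_force(self, small_noisy):
        pairs = (("A", "B"), ("B", "C"))
        prof = interchain_contact_profile(small_noisy, chain_pairs=pairs, cutoff=0.45)
        oracle = brute_contact_profile(small_noisy, pairs, 0.45)
        assert np.array_equal(prof.probability, oracle)

    def test_nonbonded_map_equals_brute_force(self, small_noisy):
        pairs = (("A", "B"),)
        m = nonbonded_contact_map(small_noisy, cutoff=0.45, chain_pairs=pairs)
        oracle = brute_nonbonded_map(small_noisy, pairs, 0.45)
        assert np.array_equal(m.values, oracle)
        assert np.array_equal(m.values, m.values.T)  # symmetric

    def test_hbond_map_equals_brute_force_distance_only(self, small_noisy):
        pairs = (("B", "C"),)
        m = hydrogen_bond_map(
            small_noisy, scope="inter", mode="distance", chain_pairs=pairs
        )
        oracle = brute_hbond_map_inter(small_noisy, pairs, 0.35)
        assert np.array_equal(m.values, oracle)


class TestContactProfile:
    def test_ideal_fibril_probability_one_everywhere(self, ideal_u):
        prof = interchain_contact_profile(ideal_u)
        assert np.all(prof.probability == 1.0)

    def test_displaced_chain_gives_half_probability(self, ideal_u):
        coords = ideal_u.coordinates.copy()
        n_frames = coords.shape[0]
        coords = np.concatenate([coords, coords])  # 6 frames
        d_mask = ideal_u.topology.chain_mask("D")
        for f in range(n_frames):  # displace D far away in the first half
            coords[f, d_mask] += np.array([2.0, 0.0, 0.0]) * 5
        traj = Trajectory(ideal_u.topology, coords, reference_frame=n_frames)
        prof = interchain_contact_profile(traj, chain_pairs=[("C", "D")])
        assert np.all(prof.probability == 0.5)

    def test_cutoff_monotonicity(self, small_noisy):
        cuts = (0.3, 0.45, 0.6)
        profs = [
            interchain_contact_profile(small_noisy, chain_pairs=[("A", "B")], cutoff=c).probability
            for c in cuts
        ]
        assert np.all(profs[0] <= profs[1]) and np.all(profs[1] <= profs[2])

    def test_empty_pair_list_rejected(self, ideal_u):
        with pytest.raises(ValueError):
            interchain_contact_profile(ideal_u, chain_pairs=[])


class TestHbondCriteria:
    @staticmethod
    def _two_residue_frame(o_offset, with_h=None):
        """Donor N+H in chain A residue 1; acceptor O in chain B residue 2."""
        names = ["N", "H", "CA", "O", "CA"]
        elements = ["N", "H", "C", "O", "C"]
        resnum = [1, 1, 1, 2, 2]
        chains = ["A", "A", "A", "B", "B"]
        h = with_h if with_h is not None else [0.0, 0.0, -0.10]
        coords = np.array(
            [
                [0.0, 0.0, 0.0],       # N (donor)
                h,                     # H
                [0.3, 0.0, 0.0],       # CA
                o_offset,              # O (acceptor)
                [0.3, 0.0, 1.0],       # CA chain B
            ]
        )
        top = make_toy_topology(names, elements, resnum, chains)
        return Trajectory(top, coords[None])

    def test_distance_just_beyond_cutoff_not_counted(self):
        traj = self._two_residue_frame([0.0, 0.0, -0.36])
        m = hydrogen_bond_map(traj, scope="inter", chain_pairs=[("A", "B")])
        assert m.at(1, 2) == 0.0
        at_cut = self._two_residue_frame([0.0, 0.0, -0.35])
        m2 = hydrogen_bond_map(at_cut, scope="inter", chain_pairs=[("A", "B")])
        assert m2.at(1, 2) == 1.0

    def test_angle_criterion_rejects_bent_geometry(self):
        # acceptor 45° off the N-H line at 0.30 nm
        a = 0.30 / np.sqrt(2.0)
        traj = self._two_residue_frame([a, 0.0, -a])
        dist_only = hydrogen_bond_map(
            traj, scope="inter", mode="distance", chain_pairs=[("A", "B")]
        )
        assert dist_only.at(1, 2) == 1.0
        with_angle = hydrogen_bond_map(
            traj, scope="inter", mode="distance+angle", angle_max=30.0,
            chain_pairs=[("A", "B")],
        )
        assert with_angle.at(1, 2) == 0.0

    def test_distance_only_map_dominates_angle_map(self, small_noisy):
        pairs = [("A", "B")]
        loose = hydrogen_bond_map(
            small_noisy, scope="inter", mode="distance", chain_pairs=pairs
        )
        strict = hydrogen_bond_map(
            small_noisy, scope="inter", mode="distance+angle", chain_pairs=pairs
        )
        assert np.all(loose.values >= strict.values)

    def test_intra_map_excludes_sequence_neighbours(self, ideal_u):
        m = hydrogen_bond_map(ideal_u, scope="intra")
        res = m.row_residues
        for i in range(len(res)):
            for j in range(len(res)):
                if abs(res[i] - res[j]) < 2:
                    assert m.values[i, j] == 0.0


class TestNonbondedMap:
    def test_ideal_fibril_band_on_diagonal(self, ideal_u):
        m = nonbonded_contact_map(ideal_u)
        assert np.all(np.diag(m.values) == 1.0)

    def test_separated_chains_give_zero_map(self, ideal_u):
        coords = ideal_u.coordinates.copy()
        top = ideal_u.topology
        for k, chain in enumerate(top.chain_order):
            coords[:, top.chain_mask(chain)] += np.array([0.0, 0.0, 5.0]) * k
        far = Trajectory(top, coords)
        m = nonbonded_contact_map(far)
        assert np.all(m.values == 0.0)


# ----------------------------------------------------------------------
# Secondary structure
# ----------------------------------------------------------------------

def _nerf_place(a, b, c, bond, angle_deg, torsion_deg):
    """Place the next atom from three predecessors (internal coordinates)."""
    angle = np.radians(angle_deg)
    torsion = -np.radians(torsion_deg)  # sign convention of the frame below
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone_with_torsions(n_res, phi, psi, omega=180.0):
    """Ideal backbone (N, CA, C per residue) with prescribed (φ, ψ, ω)."""
    coords = [
        np.array([0.0, 0.0, 0.0]),            # N
        np.array([0.1458, 0.0, 0.0]),         # CA
        np.array([0.1458 + 0.1525 * np.cos(np.radians(68.8)),
                  0.1525 * np.sin(np.radians(68.8)), 0.0]),  # C
    ]
    for _ in range(1, n_res):
        coords.append(_nerf_place(coords[-3], coords[-2], coords[-1], 0.1329, 116.2, psi))
        coords.append(_nerf_place(coords[-3], coords[-2], coords[-1], 0.1458, 121.7, omega))
        coords.append(_nerf_place(coords[-3], coords[-2], coords[-1], 0.1525, 111.2, phi))
    return np.array(coords)


def test_ideal_template_arms_are_fully_beta(ideal_u):
    ss = classify_secondary_structure(ideal_u)
    tpl = build_ideal_chain("U")
    interior_arms = [
        r for r in tpl.arm_residues()
        if tpl.segments.get(r - 1) == tpl.segments[r] == tpl.segments.get(r + 1)
    ]
    for r in interior_arms:
        i = list(ss.residue_numbers).index(r)
        assert ss.beta[i] == 1.0, f"residue {r} should be β"


def test_template_turn_residues_are_unstructured(ideal_u, ideal_s):
    for traj, turns in ((ideal_u, range(27, 31)), (ideal_s, range(21, 24))):
        ss = classify_secondary_structure(traj)
        for r in turns:
            i = list(ss.residue_numbers).index(r)
            assert ss.coil[i] == 1.0, f"residue {r} should be coil"


def test_alpha_helix_fixture_classified_as_helix():
    coords = build_backbone_with_torsions(8, phi=-60.0, psi=-45.0)
    n_res = 8
    names = ["N", "CA", "C"] * n_res
    elements = ["N", "C", "C"] * n_res
    resnum = sum([[i + 1] * 3 for i in range(n_res)], [])
    top = make_toy_topology(names, elements, resnum, ["A"] * (3 * n_res))
    traj = Trajectory(top, coords[None])
    ss = classify_secondary_structure(traj)
    interior = (ss.residue_numbers >= 2) & (ss.residue_numbers <= n_res - 1)
    assert np.all(ss.helix[interior] == 1.0)
    assert np.all(ss.beta == 0.0)  # single chain: no inter-chain H-bonds


def test_beta_needs_interchain_hbond_partner(ideal_u):
    """A lone chain with β dihedrals is unstructured without a partner."""
    top = ideal_u.topology
    lone = ideal_u.select_atoms(top.chain_mask("A"))
    ss = classify_secondary_structure(lone)
    assert np.all(ss.beta == 0.0)


def test_probabilities_are_well_formed(noisy_u):
    ss = classify_secondary_structure(noisy_u)
    for arr in (ss.beta, ss.helix, ss.coil):
        assert np.all((arr >= 0.0) & (arr <= 1.0))
    assert np.allclose(ss.beta + ss.helix + ss.coil, 1.0)
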