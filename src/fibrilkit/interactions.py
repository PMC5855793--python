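"""Inter-chain contact, hydrogen-bond and secondary-structure statistics.

All outputs are probabilities over frames (and over the designated chain
pairs): a contact/H-bond either exists in a frame or it does not, and
the map entry is the fraction of observations in which it exists.

Conventions
-----------
* "Contact" means minimum heavy-atom distance ≤ cutoff (default
  0.45 nm).
* Hydrogen bonds use a donor(N)–acceptor(O) distance cutoff (default
  0.35 nm) and, when explicit hydrogens are present, an H–donor–acceptor
  angle cutoff (default 30°); a distance-only mode is available.
* Inter-chain statistics average over the interior adjacent chain pairs
  (B-C and C-D for a pentamer) unless chain pairs are given explicitly;
  intra-chain statistics use the central chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import FibrilTopology, StructureError, TopologyError, Trajectory

__all__ = [
    "ResidueMatrix",
    "ContactProfile",
    "SecondaryStructureProfile",
    "interchain_contact_profile",
    "hydrogen_bond_map",
    "nonbonded_contact_map",
    "classify_secondary_structure",
    "default_interior_pairs",
]

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 0.45   # nm
HBOND_CUTOFF = 0.35     # nm
HBOND_ANGLE_MAX = 30.0  # degrees, H–donor–acceptor
INTRA_MIN_SEPARATION = 2  # exclude |i-j| < 2 for intra-chain statistics

# β and helix regions of the simplified dihedral classifier (degrees)
BETA_PHI = (-180.0, -90.0)
BETA_PSI = ((90.0, 180.0), (-180.0, -170.0))
HELIX_CENTER = (-60.0, -45.0)
HELIX_TOL = 30.0


@dataclass
class ResidueMatrix:
    """Residue-by-residue probability (or area) matrix.

    Rows index ``row_residues``, columns ``col_residues``.  H-bond maps
    are donor→acceptor and may be asymmetric; non-bonded contact maps
    are symmetrised over the two chain orientations.
    """

    values: np.ndarray
    row_residues: np.ndarray
    col_residues: np.ndarray
    kind: str = ""
    chain_pairs: tuple = ()
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_residues = np.asarray(self.row_residues, dtype=int)
        self.col_residues = np.asarray(self.col_residues, dtype=int)
        if self.values.shape != (len(self.row_residues), len(self.col_residues)):
            raise ValueError("matrix shape does not match residue labels")

    def at(self, res_i: int, res_j: int) -> float:
        i = int(np.flatnonzero(self.row_residues == res_i)[0])
        j = int(np.flatnonzero(self.col_residues == res_j)[0])
        return float(self.values[i, j])


@dataclass
class ContactProfile:
    """Per-residue inter-chain contact probability in [0, 1]."""

    residue_numbers: np.ndarray
    probability: np.ndarray
    chain_pairs: tuple
    cutoff: float

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any((self.probability < -1e-12) | (self.probability > 1 + 1e-12)):
            raise ValueError("contact probabilities must lie in [0, 1]")

    def value_at(self, residue_number: int) -> float:
        idx = int(np.flatnonzero(self.residue_numbers == residue_number)[0])
        return float(self.probability[idx])


def default_interior_pairs(topology: FibrilTopology) -> tuple[tuple[str, str], ...]:
    """Adjacent chain pairs excluding the two edge pairs (B-C, C-D for A..E)."""
    order = topology.chain_order
    pairs = [(order[i], order[i + 1]) for i in range(len(order) - 1)]
    if len(pairs) > 2:
        pairs = pairs[1:-1]
    return tuple(pairs)


def _check_adjacent(topology: FibrilTopology, pairs) -> None:
    order = list(topology.chain_order)
    for x, y in pairs:
        if x not in order or y not in order:
            raise TopologyError(f"unknown chain in pair ({x}, {y})")
        if abs(order.index(x) - order.index(y)) != 1:
            logger.warning("chain pair (%s, %s) is not adjacent along the fibril", x, y)


def _residue_blocks(topology: FibrilTopology, chain: str, mask: np.ndarray):
    """Atom indices of each residue of one chain (restricted by mask)."""
    res = topology.residue_numbers
    return [np.flatnonzero(topology.residue_mask(chain, r) & mask) for r in res]


def _min_dist_matrix(
    coords: np.ndarray, blocks_x: list[np.ndarray], blocks_y: list[np.ndarray]
) -> np.ndarray:
    """Minimum inter-atom distance for every residue pair (i of X, j of Y)."""
    idx_x = np.concatenate(blocks_x)
    idx_y = np.concatenate(blocks_y)
    d = np.linalg.norm(coords[idx_x, None, :] - coords[None, idx_y, :], axis=2)
    out = np.empty((len(blocks_x), len(blocks_y)))
    row_edges = np.cumsum([0] + [len(b) for b in blocks_x])
    col_edges = np.cumsum([0] + [len(b) for b in blocks_y])
    for i in range(len(blocks_x)):
        sub = d[row_edges[i] : row_edges[i + 1]]
        for j in range(len(blocks_y)):
            out[i, j] = sub[:, col_edges[j] : col_edges[j + 1]].min()
    return out


# ----------------------------------------------------------------------
# Contact probability
# ----------------------------------------------------------------------

def interchain_contact_profile(
    traj: Trajectory,
    chain_pairs=None,
    cutoff: float = CONTACT_CUTOFF,
) -> ContactProfile:
    """Per-residue inter-chain contact probability.

    A residue r of chain X contacts chain Y in a frame iff the minimum
    heavy-atom distance between residue r of X and any residue of Y is
    ≤ cutoff.  The probability is the fraction of frames, averaged over
    the two orientations of each pair and over the designated pairs
    (default: the interior pairs).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    if chain_pairs is None:
        chain_pairs = default_interior_pairs(top)
    chain_pairs = tuple(tuple(p) for p in chain_pairs)
    if not chain_pairs:
        raise ValueError("no chain pairs given")
    _check_adjacent(top, chain_pairs)

    heavy = top.heavy_mask
    res = top.residue_numbers
    counts = np.zeros(len(res))
    n_obs = 0
    for x, y in chain_pairs:
        bx = _residue_blocks(top, x, heavy)
        by = _residue_blocks(top, y, heavy)
        for f in range(traj.n_frames):
            m = _min_dist_matrix(traj.coordinates[f], bx, by)
            counts += (m.min(axis=1) <= cutoff)  # residue of X vs chain Y
            counts += (m.min(axis=0) <= cutoff)  # residue of Y vs chain X
            n_obs += 2
    return ContactProfile(
        residue_numbers=res,
        probability=counts / n_obs,
        chain_pairs=chain_pairs,
        cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# Hydrogen bonds
# ----------------------------------------------------------------------

def _donors_acceptors(topology: FibrilTopology, chain: str):
    """Donor N (with attached H if present) and acceptor O indices per residue."""
    res = topology.residue_numbers
    donors, hydrogens, acceptors = [], [], []
    for r in res:
        m = topology.residue_mask(chain, r)
        n_idx = np.flatnonzero(m & (topology.element == "N"))
        o_idx = np.flatnonzero(m & (topology.element == "O"))
        h_idx = np.flatnonzero(m & (topology.element == "H"))
        donors.append(n_idx)
        acceptors.append(o_idx)
        hydrogens.append(h_idx)
    return donors, hydrogens, acceptors


def _hbond_exists(
    coords: np.ndarray,
    donor_idx: np.ndarray,
    h_idx: np.ndarray,
    acc_idx: np.ndarray,
    cutoff: float,
    angle_max: float | None,
) -> bool:
    """Any donor–acceptor pair within cutoff (and H–D–A angle, if used)."""
    if len(donor_idx) == 0 or len(acc_idx) == 0:
        return False
    d_pos = coords[donor_idx]
    a_pos = coords[acc_idx]
    dist = np.linalg.norm(d_pos[:, None, :] - a_pos[None, :, :], axis=2)
    ok = dist <= cutoff
    if not np.any(ok):
        return False
    if angle_max is None or len(h_idx) == 0:
        return True
    cos_max = np.cos(np.radians(angle_max))
    for di, ai in zip(*np.nonzero(ok)):
        d = d_pos[di]
        a = a_pos[ai]
        # hydrogens bonded to this donor (within 0.125 nm)
        h_near = coords[h_idx][np.linalg.norm(coords[h_idx] - d, axis=1) <= 0.125]
        for h in h_near:
            dh = h - d
            da = a - d
            c = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
            if c >= cos_max:
                return True
    return False


def hydrogen_bond_map(
    traj: Trajectory,
    scope: str = "inter",
    cutoff: float = HBOND_CUTOFF,
    angle_max: float | None = HBOND_ANGLE_MAX,
    mode: str = "distance+angle",
    chain_pairs=None,
    chain: str | None = None,
) -> ResidueMatrix:
    """Residue-by-residue hydrogen-bond probability map.

    Entry (i, j) is the probability that a bond with *donor* residue i
    and *acceptor* residue j exists.  For ``scope="inter"`` both
    directions of each designated adjacent chain pair count as the same
    (i, j) relation; for ``scope="intra"`` bonds are searched within one
    chain (default: the central chain) with sequence neighbours
    |i − j| < 2 excluded.

    ``mode="distance"`` ignores the H–donor–acceptor angle; otherwise the
    angle criterion applies whenever explicit hydrogens exist (with a
    logged notice when they do not).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("distance", "distance+angle"):
        raise ValueError("mode must be 'distance' or 'distance+angle'")
    top = traj.topology
    res = top.residue_numbers
    n_res = len(res)
    use_angle = angle_max if mode == "distance+angle" else None
    if use_angle is not None and not top.has_hydrogens:
        logger.info("no explicit hydrogens: falling back to distance-only H-bond criterion")
        use_angle = None
    if not np.any(top.element == "N") or not np.any(top.element == "O"):
        raise StructureError("no hydrogen-bond donors/acceptors in topology")

    counts = np.zeros((n_res, n_res))
    n_obs = 0
    if scope == "inter":
        if chain_pairs is None:
            chain_pairs = default_interior_pairs(top)
        chain_pairs = tuple(tuple(p) for p in chain_pairs)
        _check_adjacent(top, chain_pairs)
        per_chain = {c: _donors_acceptors(top, c) for c in top.chain_order}
        for x, y in chain_pairs:
            dx, hx, ax = per_chain[x]
            dy, hy, ay = per_chain[y]
            for f in range(traj.n_frames):
                c = traj.coordinates[f]
                for i in range(n_res):
                    for j in range(n_res):
                        hit = _hbond_exists(c, dx[i], hx[i], ay[j], cutoff, use_angle) or _hbond_exists(
                            c, dy[i], hy[i], ax[j], cutoff, use_angle
                        )
                        counts[i, j] += hit
                n_obs += 1
    elif scope == "intra":
        if chain is None:
            chain = top.chain_order[len(top.chain_order) // 2]
        d_, h_, a_ = _donors_acceptors(top, chain)
        for f in range(traj.n_frames):
            c = traj.coordinates[f]
            for i in range(n_res):
                for j in range(n_res):
                    if abs(int(res[i]) - int(res[j])) < INTRA_MIN_SEPARATION:
                        continue
                    counts[i, j] += _hbond_exists(c, d_[i], h_[i], a_[j], cutoff, use_angle)
            n_obs += 1
    else:
        raise ValueError("scope must be 'inter' or 'intra'")

    return ResidueMatrix(
        values=counts / max(n_obs, 1),
        row_residues=res,
        col_residues=res,
        kind=f"hbond-{scope}",
        chain_pairs=tuple(chain_pairs) if scope == "inter" else (chain,),
        cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# Non-bonded contact map
# ----------------------------------------------------------------------

def nonbonded_contact_map(
    traj: Trajectory,
    cutoff: float = CONTACT_CUTOFF,
    chain_pairs=None,
) -> ResidueMatrix:
    """Inter-chain non-bonded contact probability map.

    Entry (i, j) is the probability (over frames and the designated
    adjacent chain pairs) that any heavy-atom pair between residue i of
    one chain and residue j of the neighbouring chain lies within the
    cutoff; symmetric after averaging both orientations.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    if chain_pairs is None:
        chain_pairs = default_interior_pairs(top)
    chain_pairs = tuple(tuple(p) for p in chain_pairs)
    _check_adjacent(top, chain_pairs)
    heavy = top.heavy_mask
    res = top.residue_numbers
    counts = np.zeros((len(res), len(res)))
    n_obs = 0
    for x, y in chain_pairs:
        bx = _residue_blocks(top, x, heavy)
        by = _residue_blocks(top, y, heavy)
        for f in range(traj.n_frames):
            m = _min_dist_matrix(traj.coordinates[f], bx, by) <= cutoff
            counts += m
            counts += m.T
            n_obs += 2
    return ResidueMatrix(
        values=counts / n_obs,
        row_residues=res,
        col_residues=res,
        kind="nonbonded-contacts",
        chain_pairs=chain_pairs,
        cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# Simplified secondary-structure classifier
# ----------------------------------------------------------------------

@dataclass
class SecondaryStructureProfile:
    """Per-residue class probabilities over frames and chains."""

    residue_numbers: np.ndarray
    beta: np.ndarray
    helix: np.ndarray
    coil: np.ndarray

    def __post_init__(self) -> None:
        total = self.beta + self.helix + self.coil
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("class probabilities must sum to 1 per residue")


def _dihedral_batch(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def _in_beta(phi: float | None, psi: float | None) -> bool:
    phi_ok = phi is None or (BETA_PHI[0] <= phi <= BETA_PHI[1])
    psi_ok = psi is None or any(lo <= psi <= hi for lo, hi in BETA_PSI)
    if phi is None and psi is None:
        return False
    return phi_ok and psi_ok


def _in_helix(phi: float | None, psi: float | None) -> bool:
    if phi is None or psi is None:
        return False
    dphi = (phi - HELIX_CENTER[0] + 180.0) % 360.0 - 180.0
    dpsi = (psi - HELIX_CENTER[1] + 180.0) % 360.0 - 180.0
    return abs(dphi) <= HELIX_TOL and abs(dpsi) <= HELIX_TOL


def classify_secondary_structure(
    traj: Trajectory,
    hbond_cutoff: float = HBOND_CUTOFF,
) -> SecondaryStructureProfile:
    """Simplified per-residue secondary-structure probabilities.

    A residue is structured-β in a frame iff its (φ, ψ) falls in the β
    region AND it participates in at least one inter-chain backbone
    hydrogen bond (donor N or acceptor O within ``hbond_cutoff`` of a
    partner in another chain, distance criterion).  It is helical iff
    (φ, ψ) is within 30° of (−60°, −45°).  Otherwise it is unstructured.
    Chain-terminal residues are classified from whichever of φ/ψ exists.
    Probabilities average over frames and chains.
    """
    top = traj.topology
    res = top.residue_numbers
    n_res = len(res)
    beta = np.zeros(n_res)
    helix = np.zeros(n_res)
    n_obs = 0

    # backbone index tables per chain, residue-ordered
    tables = {}
    for chain in top.chain_order:
        idx = {}
        for name in ("N", "CA", "C", "O"):
            rows = []
            for r in res:
                m = np.flatnonzero(top.residue_mask(chain, r) & (top.atom_name == name))
                rows.append(int(m[0]) if len(m) else -1)
            idx[name] = np.array(rows)
        tables[chain] = idx

    for f in range(traj.n_frames):
        c = traj.coordinates[f]
        # inter-chain backbone H-bond participation per (chain, residue)
        participates = {}
        for ci, chain in enumerate(top.chain_order):
            part = np.zeros(n_res, dtype=bool)
            for other in top.chain_order:
                if other == chain:
                    continue
                n_self = c[tables[chain]["N"]]
                o_self = c[tables[chain]["O"]]
                n_other = c[tables[other]["N"]]
                o_other = c[tables[other]["O"]]
                d_no = np.linalg.norm(n_self[:, None] - o_other[None, :], axis=2)
                d_on = np.linalg.norm(o_self[:, None] - n_other[None, :], axis=2)
                part |= (d_no.min(axis=1) <= hbond_cutoff) | (d_on.min(axis=1) <= hbond_cutoff)
            participates[chain] = part

        for chain in top.chain_order:
            t = tables[chain]
            for ri in range(n_res):
                phi = psi = None
                if ri > 0 and t["C"][ri - 1] >= 0:
                    phi = float(
                        _dihedral_batch(
                            c[t["C"][ri - 1]], c[t["N"][ri]], c[t["CA"][ri]], c[t["C"][ri]]
                        )
                    )
                if ri < n_res - 1 and t["N"][ri + 1] >= 0:
                    psi = float(
                        _dihedral_batch(
                            c[t["N"][ri]], c[t["CA"][ri]], c[t["C"][ri]], c[t["N"][ri + 1]]
                        )
                    )
                if _in_beta(phi, psi) and participates[chain][ri]:
                    beta[ri] += 1
                elif _in_helix(phi, psi):
                    helix[ri] += 1
            n_obs += 1

    beta /= n_obs
    helix /= n_obs
    return SecondaryStructureProfile(
        residue_numbers=res,
        beta=beta,
        helix=helix,
        coil=1.0 - beta - helix,
    )
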