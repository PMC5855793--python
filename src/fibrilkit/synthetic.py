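"""Synthetic cross-β fibril trajectory generator.

Builds ground-truth pentamer assemblies of a 26-residue peptide
(numbered 17–42, the Aβ17–42 window) in either the U-shaped fold (two
β-arms joined by one turn) or the S-shaped fold (three β-arms joined by
two turns), stacks ``n_chains`` copies along the fibril axis at the
cross-β rise, and perturbs them with controllable disorder: isotropic
Gaussian coordinate noise, per-chain tilt, a uniform stacking-direction
tilt, and an optional planted collective mode whose amplitude varies
over frames.

Geometric idealisations
-----------------------
* The Cα trace of each chain is an exactly planar polyline with 0.38 nm
  spacing; arms are straight, turns are circular-arc bends.
* Amide N and carbonyl C are placed by fixed local-frame offsets tuned
  so that arm-interior backbone dihedrals sit at (φ, ψ) ≈ (−139°, +135°)
  (ideal β); turn residues use the mirror placement, which puts them in
  a clearly non-β, non-helical region.
* The carbonyl O and amide H of each residue are placed on the
  nitrogen's stacking column (O at N + 0.19 nm·ẑ, H at N − 0.10 nm·ẑ),
  so that every in-register inter-chain N–H···O pair has donor–acceptor
  distance exactly ``rise − 0.19`` = 0.29 nm and a perfectly linear
  H–D–A geometry.  This idealises the cross-β hydrogen-bond ladder at
  the cost of a non-physical C–O bond vector.
* Side chains are reduced to a single Cβ pseudo-atom (absent for
  glycine).

The fibril axis of generated data is the laboratory z axis of frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    FibrilTopology,
    Trajectory,
    TopologyError,
    element_from_atom_name,
)

__all__ = [
    "GeneratorParams",
    "PlantedMode",
    "ChainTemplate",
    "build_ideal_chain",
    "generate_trajectory",
    "plant_hbond_register",
    "make_cterminal_mode",
    "sinusoid_amplitudes",
    "AB17_42_SEQUENCE",
]

#: Aβ residues 17–42, three-letter codes (L17 .. A42).
AB17_42_SEQUENCE = (
    "LEU", "VAL", "PHE", "PHE", "ALA", "GLU", "ASP", "VAL", "GLY", "SER",
    "ASN", "LYS", "GLY", "ALA", "ALA", "ILE", "GLY", "LEU", "MET", "VAL",
    "GLY", "GLY", "VAL", "VAL", "ILE", "ALA",
)
FIRST_RESIDUE = 17

CA_SPACING = 0.38          # nm, consecutive Cα–Cα distance
DEFAULT_RISE = 0.48        # nm, cross-β inter-chain spacing
O_COLUMN_OFFSET = 0.19     # nm, carbonyl O above its residue's N
H_COLUMN_OFFSET = 0.10     # nm, amide H below its residue's N
CB_BOND = 0.153            # nm, Cα–Cβ pseudo-bond

# Local-frame offsets of amide N and carbonyl C relative to Cα, in the
# (tangent, in-plane normal, axis) frame of the Cα path, plus the
# alternating out-of-plane Cα pleat of the two-residue screw period.
# Tuned once so that a straight arm yields (φ, ψ) = (−139°, +135°) with
# near-standard N–Cα / Cα–C bond lengths (see docs/methods.md).  Turn
# residues use the z-mirrored offsets.
N_OFFSET = (-0.13671, 0.02544, 0.04383)
C_OFFSET = (0.14871, -0.00793, -0.03284)
CA_PLEAT = 0.04543

# Chain labels along the fibril axis.
_CHAIN_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees (IUPAC convention)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


# ----------------------------------------------------------------------
# Chain template
# ----------------------------------------------------------------------

#: Segment layout per shape: (label, first_residue, last_residue).
#: Arm extents follow the strand definitions of the two folds
#: (U: strands 18–26 and 31–40; S: central strand 24–33, C-terminal
#: strand 36–40), extended to the window termini where the fold is
#: geometrically straight.
_SEGMENTS = {
    "U": (("beta1", 17, 26), ("turn1", 27, 30), ("beta2", 31, 42)),
    "S": (
        ("beta1", 17, 20),
        ("turn1", 21, 23),
        ("beta2", 24, 33),
        ("turn2", 34, 35),
        ("beta3", 36, 42),
    ),
}


@dataclass
class ChainTemplate:
    """Ideal single-chain backbone template (nm, Cα path in the z=0 plane)."""

    shape: str
    residue_numbers: np.ndarray      # (n_res,)
    residue_names: tuple[str, ...]
    segments: dict[int, str]         # residue number -> segment label
    atom_name: np.ndarray            # (n_atoms,)
    residue_number: np.ndarray       # (n_atoms,)
    coordinates: np.ndarray          # (n_atoms, 3)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def arm_residues(self) -> list[int]:
        return [r for r, seg in self.segments.items() if seg.startswith("beta")]

    def turn_residues(self) -> list[int]:
        return [r for r, seg in self.segments.items() if seg.startswith("turn")]


def _ca_path_headings(shape: str, n_residues: int) -> np.ndarray:
    """Heading angle (degrees, in the xy plane) of each Cα→Cα step.

    Arm steps run straight (headings 0°, 180°, 0° for successive arms);
    each turn reverses the heading through evenly spaced intermediate
    headings, with alternating bend sense (which is what makes the
    three-arm fold an S rather than a spiral).
    """
    segments = _SEGMENTS[shape]
    arm_headings: dict[str, float] = {}
    h, sense, bends = 0.0, +1.0, {}
    for label, _, _ in segments:
        if label.startswith("beta"):
            arm_headings[label] = h
        else:
            bends[label] = sense
            h = h + sense * 180.0
            sense = -sense
    headings = np.zeros(n_residues - 1)
    i = 0
    seg_list = list(segments)
    for s_idx, (label, lo, hi) in enumerate(seg_list):
        if label.startswith("beta"):
            # steps internal to the arm (from r to r+1, both inside)
            n_steps = hi - lo
            headings[i : i + n_steps] = arm_headings[label]
            i += n_steps
        else:
            # turn of residues lo..hi spans steps (lo-1→lo) .. (hi→hi+1)
            n_steps = hi - lo + 2
            h0 = arm_headings[seg_list[s_idx - 1][0]]
            h1 = h0 + bends[label] * 180.0
            headings[i : i + n_steps] = np.linspace(h0, h1, n_steps + 1)[1:]
            i += n_steps
    assert i == n_residues - 1
    return headings


def _ca_path(shape: str, n_residues: int) -> np.ndarray:
    """Pleated Cα path: planar polyline plus alternating ±z pleat.

    The in-plane spacing is shrunk so that every consecutive Cα–Cα
    distance is exactly ``CA_SPACING`` (the z pleat alternates sign, so
    the correction is the same for arm and turn steps).
    """
    headings = np.radians(_ca_path_headings(shape, n_residues))
    in_plane = np.sqrt(CA_SPACING**2 - (2.0 * CA_PLEAT) ** 2)
    steps = in_plane * np.stack(
        [np.cos(headings), np.sin(headings), np.zeros_like(headings)], axis=1
    )
    path = np.zeros((n_residues, 3))
    path[1:] = np.cumsum(steps, axis=0)
    path[:, 2] += CA_PLEAT * (-1.0) ** np.arange(n_residues)
    return path


def build_ideal_chain(shape: str, n_residues: int = 26) -> ChainTemplate:
    """Build one ideal chain of backbone atoms (N, H, CA, C, O, Cβ).

    ``shape`` is ``"U"`` (two antiparallel arms + one turn) or ``"S"``
    (three arms + two turns).  Consecutive Cα–Cα distance is 0.38 nm.
    Arm-interior residues have β-sheet backbone dihedrals; turn residues
    have non-β, non-helical (mirrored) dihedrals.
    """
    shape = shape.upper()
    if shape not in _SEGMENTS:
        raise ValueError(f"unsupported shape {shape!r}: expected 'U' or 'S'")
    if n_residues != len(AB17_42_SEQUENCE):
        raise ValueError(
            f"canonical templates are defined for {len(AB17_42_SEQUENCE)} residues"
        )

    res_numbers = np.arange(FIRST_RESIDUE, FIRST_RESIDUE + n_residues)
    seg_of: dict[int, str] = {}
    for label, lo, hi in _SEGMENTS[shape]:
        for r in range(lo, hi + 1):
            seg_of[r] = label

    ca = _ca_path(shape, n_residues)
    # Per-residue tangent: mean of adjacent step directions of the
    # in-plane (xy) projection of the path.
    ca_xy = ca.copy()
    ca_xy[:, 2] = 0.0
    diffs = np.diff(ca_xy, axis=0)
    diffs /= np.linalg.norm(diffs, axis=1, keepdims=True)
    tangents = np.zeros_like(ca)
    tangents[0] = diffs[0]
    tangents[-1] = diffs[-1]
    tangents[1:-1] = diffs[:-1] + diffs[1:]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    zhat = np.array([0.0, 0.0, 1.0])
    normals = np.cross(zhat, tangents)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    atom_names: list[str] = []
    atom_res: list[int] = []
    coords: list[np.ndarray] = []
    n_off = np.asarray(N_OFFSET)
    c_off = np.asarray(C_OFFSET)
    for i, r in enumerate(res_numbers):
        t, n = tangents[i], normals[i]
        # Two-residue screw period (180° rotation about the strand axis),
        # as in a real β-strand: transverse offsets alternate sign.
        par = 1.0 if i % 2 == 0 else -1.0
        # Turn residues use the z-mirrored (improper) frame, which lands
        # their dihedrals in a non-β, non-helical region.
        chir = 1.0 if seg_of[r].startswith("beta") else -1.0
        frame = np.stack([t, par * n, par * chir * zhat], axis=1)
        pos_n = ca[i] + frame @ n_off
        pos_c = ca[i] + frame @ c_off
        pos_o = pos_n + np.array([0.0, 0.0, O_COLUMN_OFFSET])
        pos_h = pos_n - np.array([0.0, 0.0, H_COLUMN_OFFSET])
        # Cβ alternates sides of the sheet plane along the strand.
        cb_dir = par * (0.55 * n - 0.835 * chir * zhat)
        cb_dir = cb_dir / np.linalg.norm(cb_dir)
        pos_cb = ca[i] + CB_BOND * cb_dir
        names = ["N", "H", "CA", "C", "O"]
        positions = [pos_n, pos_h, ca[i], pos_c, pos_o]
        if AB17_42_SEQUENCE[i] != "GLY":
            names.append("CB")
            positions.append(pos_cb)
        atom_names.extend(names)
        atom_res.extend([int(r)] * len(names))
        coords.extend(positions)

    return ChainTemplate(
        shape=shape,
        residue_numbers=res_numbers,
        residue_names=AB17_42_SEQUENCE,
        segments=seg_of,
        atom_name=np.array(atom_names, dtype="U6"),
        residue_number=np.array(atom_res, dtype=int),
        coordinates=np.array(coords, dtype=float),
    )


# ----------------------------------------------------------------------
# Planted collective modes
# ----------------------------------------------------------------------

@dataclass
class PlantedMode:
    """A unit collective displacement field over Cα sites plus amplitudes.

    ``directions`` has one 3-vector per Cα of the whole assembly
    (n_chains × n_residues rows, chain-major in stacking order) and unit
    overall Euclidean norm.  ``amplitudes`` (nm) has one entry per frame.
    """

    directions: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise ValueError("directions must be (n_calpha, 3)")
        norm = np.linalg.norm(self.directions)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError(f"planted mode must have unit overall norm, got {norm}")


def ideal_calpha_positions(
    shape: str, n_chains: int, n_residues: int = 26, rise: float = DEFAULT_RISE
) -> np.ndarray:
    """Cα coordinates of the ideal stacked assembly, chain-major."""
    template = build_ideal_chain(shape, n_residues)
    ca = template.coordinates[template.atom_name == "CA"]
    return np.concatenate(
        [ca + k * rise * np.array([0.0, 0.0, 1.0]) for k in range(n_chains)], axis=0
    )


def _project_out_rigid(field_: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Remove the rigid-body (translation + rotation) component of a field."""
    centred = positions - positions.mean(axis=0)
    basis = []
    for d in np.eye(3):
        basis.append(np.tile(d, (len(positions), 1)))
    for axis in np.eye(3):
        basis.append(np.cross(np.tile(axis, (len(positions), 1)), centred))
    flat = field_.ravel().copy()
    # Gram-Schmidt over the 6 rigid generators
    ortho = []
    for b in basis:
        v = b.ravel().astype(float)
        for o in ortho:
            v = v - (v @ o) * o
        n = np.linalg.norm(v)
        if n > 1e-12:
            ortho.append(v / n)
    for o in ortho:
        flat -= (flat @ o) * o
    return flat.reshape(-1, 3)


def make_cterminal_mode(
    n_chains: int,
    n_residues: int = 26,
    residues: Sequence[int] = range(36, 43),
    chain_index: int = -1,
    direction: Sequence[float] = (1.0, 0.0, 0.0),
    shape: str = "U",
    project_rigid: bool = True,
) -> np.ndarray:
    """Unit displacement field localized on C-terminal Cαs of one chain.

    Returns a (n_chains·n_residues, 3) array suitable for
    :class:`PlantedMode`.  By default the mode pushes residues 36–42 of
    the last chain laterally — the canonical 'C-terminal fraying'
    fixture — with the rigid-body (global translation/rotation)
    component projected out, so superposition-based analyses see the
    whole planted motion as internal distortion.
    """
    field_ = np.zeros((n_chains * n_residues, 3))
    chain_index = chain_index % n_chains
    res_numbers = np.arange(FIRST_RESIDUE, FIRST_RESIDUE + n_residues)
    d = np.asarray(direction, dtype=float)
    for r in residues:
        pos = chain_index * n_residues + int(np.flatnonzero(res_numbers == r)[0])
        field_[pos] = d
    if project_rigid:
        field_ = _project_out_rigid(
            field_, ideal_calpha_positions(shape, n_chains, n_residues)
        )
    field_ /= np.linalg.norm(field_)
    return field_


def sinusoid_amplitudes(
    n_frames: int,
    amplitude: float,
    cycles: float = 3.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sinusoidal amplitude series (nm) with optional Gaussian jitter."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    amps = amplitude * np.sin(2.0 * np.pi * cycles * t / max(n_frames, 1))
    if jitter > 0:
        amps = amps + jitter * rng.standard_normal(n_frames)
    return amps


# ----------------------------------------------------------------------
# Trajectory generation
# ----------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Conditions of a synthetic fibril ensemble.

    Angles in degrees, lengths in nm.  ``chain_tilt`` rotates each chain
    about its own centroid (about the x axis) — a local-disorder dial
    that does not move the stacking direction; ``stack_tilt`` tilts the
    stacking (translation) direction itself away from z, so that the
    order parameter of the ideal geometry is exactly cos(stack_tilt).
    Frame 0 carries no noise, mode displacement or chain tilt: it is the
    ideal reference that defines the fibril axis.
    """

    shape: str = "U"
    n_chains: int = 5
    n_residues: int = 26
    rise: float = DEFAULT_RISE
    noise_sigma: float = 0.0
    chain_tilt: float = 0.0
    stack_tilt: float = 0.0
    planted_mode: PlantedMode | None = None
    n_frames: int = 1
    seed: int = 0
    ideal_frame0: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be ≥ 2")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if self.planted_mode is not None:
            expected = self.n_chains * self.n_residues
            if self.planted_mode.directions.shape[0] != expected:
                raise ValueError(
                    f"planted mode has {self.planted_mode.directions.shape[0]} "
                    f"Cα vectors, topology needs {expected}"
                )
            if len(self.planted_mode.amplitudes) != self.n_frames:
                raise ValueError("planted mode amplitude series length ≠ n_frames")


def _rotation_about_x(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _assembly_topology(template: ChainTemplate, n_chains: int) -> FibrilTopology:
    chains = _CHAIN_LABELS[:n_chains]
    n_at = len(template.atom_name)
    atom_name = np.tile(template.atom_name, n_chains)
    residue_number = np.tile(template.residue_number, n_chains)
    res_name_per_atom = np.array(
        [template.residue_names[r - FIRST_RESIDUE] for r in template.residue_number],
        dtype="U4",
    )
    residue_name = np.tile(res_name_per_atom, n_chains)
    chain_id = np.repeat(np.array(list(chains), dtype="U2"), n_at)
    element = np.array([element_from_atom_name(a) for a in atom_name], dtype="U2")
    return FibrilTopology(
        atom_name=atom_name,
        element=element,
        residue_number=residue_number,
        residue_name=residue_name,
        chain_id=chain_id,
        chain_order=tuple(chains),
    )


def generate_trajectory(params: GeneratorParams) -> Trajectory:
    """Generate a synthetic fibril trajectory, fully determined by the seed.

    Chains are copies of the shape template translated by ``rise`` along
    the stacking direction (z, tilted by ``stack_tilt``).  Per frame
    (except the ideal frame 0): the planted-mode displacement scaled by
    that frame's amplitude is added rigidly to every atom of each Cα's
    residue, each chain is rotated by ``chain_tilt`` about its centroid,
    and i.i.d. Gaussian noise of ``noise_sigma`` is added per coordinate.
    """
    template = build_ideal_chain(params.shape, params.n_residues)
    topology = _assembly_topology(template, params.n_chains)
    n_at_chain = len(template.atom_name)

    tilt = np.radians(params.stack_tilt)
    stack_dir = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    ideal = np.concatenate(
        [template.coordinates + k * params.rise * stack_dir for k in range(params.n_chains)],
        axis=0,
    )

    rng = np.random.default_rng(params.seed)
    coords = np.empty((params.n_frames, topology.n_atoms, 3))
    # Map each atom to its residue's Cα slot in the (chain-major) mode field.
    res_slot = np.concatenate(
        [
            k * params.n_residues + (template.residue_number - FIRST_RESIDUE)
            for k in range(params.n_chains)
        ]
    )
    tilt_rot = _rotation_about_x(params.chain_tilt)

    for f in range(params.n_frames):
        frame = ideal.copy()
        is_ideal = params.ideal_frame0 and f == 0
        if not is_ideal:
            if params.planted_mode is not None:
                amp = params.planted_mode.amplitudes[f]
                frame += amp * params.planted_mode.directions[res_slot]
            if params.chain_tilt != 0.0:
                for k in range(params.n_chains):
                    sl = slice(k * n_at_chain, (k + 1) * n_at_chain)
                    centroid = frame[sl].mean(axis=0)
                    frame[sl] = (frame[sl] - centroid) @ tilt_rot.T + centroid
            if params.noise_sigma > 0:
                frame = frame + params.noise_sigma * rng.standard_normal(frame.shape)
        coords[f] = frame
    return Trajectory(topology=topology, coordinates=coords, reference_frame=0)


# ----------------------------------------------------------------------
# Hydrogen-bond register fixture
# ----------------------------------------------------------------------

def plant_hbond_register(
    traj: Trajectory,
    broken_pairs: Sequence[tuple[tuple[str, str], int]] = (),
    frames: Sequence[int] | None = None,
) -> Trajectory:
    """Break selected in-register inter-chain H-bonds of a generated fibril.

    The ideal geometry places every in-register backbone N–H···O pair of
    adjacent chains at 0.29 nm donor–acceptor distance.  For each
    ``((chain_x, chain_y), residue)`` entry the acceptor carbonyl O of
    the lower chain of the pair is displaced laterally so the
    donor–acceptor distance exceeds 0.40 nm — in all frames, or only in
    ``frames`` if given.  Returns a modified copy.
    """
    top = traj.topology
    order = list(top.chain_order)
    coords = traj.coordinates.copy()
    frame_set = range(traj.n_frames) if frames is None else frames
    shift = np.array([0.0, 0.31, 0.0])
    for (cx, cy), residue in broken_pairs:
        if cx not in order or cy not in order:
            raise TopologyError(f"unknown chain in pair ({cx}, {cy})")
        if abs(order.index(cx) - order.index(cy)) != 1:
            raise TopologyError(f"pair ({cx}, {cy}) is not inter-chain adjacent")
        lower = cx if order.index(cx) < order.index(cy) else cy
        idx = np.flatnonzero(top.residue_mask(lower, residue) & (top.atom_name == "O"))
        if len(idx) != 1:
            raise TopologyError(f"chain {lower} residue {residue} has no unique O atom")
        for f in frame_set:
            coords[f, idx[0]] += shift
    return Trajectory(
        topology=top,
        coordinates=coords,
        reference_frame=traj.reference_frame,
        label=traj.label,
    )
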