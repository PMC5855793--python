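"""Superposition, fluctuation and order-parameter analyses.

The central quantity is the fibril order parameter: for each frame and
each residue number r, v_r is the vector joining the Cα of the first
chain to the Cα of the same residue in the last chain, and

    ordP = (1/N_r) Σ_r  ⟨v_r, z⟩ / (‖v_r‖ ‖z‖)

with z the fibril axis.  ordP = 1 means every cross-fibril vector is
parallel to the axis (a perfectly aligned fibre); lower values measure
distortion of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AssemblyFrame, StructureError, Trajectory

__all__ = [
    "OrdPSeries",
    "ResidueProfile",
    "kabsch_rotation",
    "kabsch_superpose",
    "superpose_trajectory",
    "compute_rmsf",
    "compute_ordp",
    "ordp_distribution",
    "radius_of_gyration",
]

#: Standard atomic masses (Da) for mass-weighted geometry.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class OrdPSeries:
    """Per-frame fibril order parameter values (dimensionless, in [−1, 1])."""

    values: np.ndarray
    convention: str
    endpoints: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("order parameter values must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())


@dataclass
class ResidueProfile:
    """Per-residue scalar profile with chain-averaged mean ± std.

    ``per_chain`` holds one row per chain (stacking order); ``mean`` and
    ``std`` are taken across chains at each residue number.
    """

    residue_numbers: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    per_chain: np.ndarray | None = None
    quantity: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.residue_numbers.shape or self.std.shape != self.mean.shape:
            raise ValueError("profile arrays must share one length")
        if np.any(self.std < -1e-12):
            raise ValueError("std must be non-negative")

    def value_at(self, residue_number: int) -> float:
        idx = np.flatnonzero(self.residue_numbers == residue_number)
        if len(idx) != 1:
            raise KeyError(f"residue {residue_number} not in profile")
        return float(self.mean[idx[0]])


# ----------------------------------------------------------------------
# Kabsch superposition
# ----------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred ``mobile`` onto ``reference``.

    Both inputs must already be centred on their centroids.  Raises
    :class:`StructureError` for degenerate (collinear) point sets.
    """
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise StructureError(
            "degenerate (collinear or coincident) selection: rotation is "
            "not uniquely determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def kabsch_superpose(
    mobile: AssemblyFrame,
    reference: AssemblyFrame,
    selection: np.ndarray | None = None,
) -> tuple[AssemblyFrame, float]:
    """Least-squares rigid superposition of one frame onto another.

    ``selection`` is a boolean mask or index array over atoms (the same
    atoms in both frames); default all atoms.  Returns the transformed
    frame (all atoms moved) and the RMSD (nm) over the selection.
    """
    sel = np.arange(mobile.topology.n_atoms) if selection is None else np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if len(sel) < 3:
        raise StructureError("superposition needs at least 3 selected atoms")
    mob_sel = mobile.coordinates[sel]
    ref_sel = reference.coordinates[sel]
    mob_c = mob_sel.mean(axis=0)
    ref_c = ref_sel.mean(axis=0)
    rot = kabsch_rotation(mob_sel - mob_c, ref_sel - ref_c)
    moved = (mobile.coordinates - mob_c) @ rot.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((moved[sel] - ref_sel) ** 2, axis=1))))
    return (
        AssemblyFrame(mobile.topology, moved, frame_index=mobile.frame_index, label=mobile.label),
        rmsd,
    )


def superpose_trajectory(
    traj: Trajectory, fit_selection: np.ndarray | None = None
) -> np.ndarray:
    """All frames Cα-superposed (or per ``fit_selection``) onto the reference.

    Returns a new coordinate array; the trajectory is not modified.
    """
    if fit_selection is None:
        fit_selection = traj.topology.calpha_indices()
    sel = np.asarray(fit_selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    ref = traj.coordinates[traj.reference_frame]
    ref_sel = ref[sel]
    ref_c = ref_sel.mean(axis=0)
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        mob_sel = traj.coordinates[f][sel]
        if np.array_equal(mob_sel, ref_sel):
            # already aligned (e.g. ideal generated frames): keep exact
            out[f] = traj.coordinates[f]
            continue
        mob_c = mob_sel.mean(axis=0)
        rot = kabsch_rotation(mob_sel - mob_c, ref_sel - ref_c)
        out[f] = (traj.coordinates[f] - mob_c) @ rot.T + ref_c
    return out


# ----------------------------------------------------------------------
# RMSF
# ----------------------------------------------------------------------

def compute_rmsf(
    traj: Trajectory,
    fit_selection: np.ndarray | None = None,
    atoms: str = "heavy",
) -> ResidueProfile:
    """Per-residue RMSF (nm), averaged over chains (mean ± std).

    All frames are first superposed onto the reference over
    ``fit_selection`` (default: all Cα).  The per-atom RMSF is the root
    mean square deviation from the time-average position; residues
    average their selected atoms (``atoms``: "heavy" or "calpha"), and
    the profile reports mean ± std across chains at each residue number.
    """
    if traj.n_frames < 2:
        raise StructureError("RMSF undefined for a single frame")
    if atoms not in ("heavy", "calpha"):
        raise ValueError("atoms must be 'heavy' or 'calpha'")
    top = traj.topology
    coords = superpose_trajectory(traj, fit_selection)
    # deviations from the reference frame keep the static case exactly 0
    dev = coords - coords[traj.reference_frame]
    dev -= dev.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))

    atom_mask = top.heavy_mask if atoms == "heavy" else (top.atom_name == "CA")
    res_numbers = top.residue_numbers
    per_chain = np.empty((top.n_chains, len(res_numbers)))
    for ci, chain in enumerate(top.chain_order):
        for ri, r in enumerate(res_numbers):
            m = top.residue_mask(chain, r) & atom_mask
            per_chain[ci, ri] = per_atom[m].mean()
    return ResidueProfile(
        residue_numbers=res_numbers,
        mean=per_chain.mean(axis=0),
        std=per_chain.std(axis=0),
        per_chain=per_chain,
        quantity="RMSF",
        units="nm",
    )


# ----------------------------------------------------------------------
# Order parameter
# ----------------------------------------------------------------------

def _stacking_axis(coords: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Mean stacking vector: average over residues of Cα(last) − Cα(first)."""
    top = traj.topology
    first, last = top.chain_order[0], top.chain_order[-1]
    v = coords[top.calpha_indices(last)] - coords[top.calpha_indices(first)]
    axis = v.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise StructureError("stacking axis is undefined (zero mean vector)")
    return axis / norm


def compute_ordp(
    traj: Trajectory,
    convention: str = "reference-fit",
    axis: np.ndarray | str | None = None,
) -> OrdPSeries:
    """Fibril order parameter per frame.

    convention
        ``"reference-fit"`` (default): every frame is Cα-superposed onto
        the reference frame and compared against a fixed axis.
        ``"per-frame"``: frames are used as-is and the axis is the mean
        stacking vector recomputed in each frame.
    axis
        Fixed axis for the reference-fit convention: a 3-vector,
        ``"z"``/None for the laboratory z axis of the reference frame
        (the generated-data convention), or ``"stacking"`` for the mean
        stacking vector of the reference frame (the right choice for
        loaded structures with arbitrary orientation).
    """
    top = traj.topology
    if top.n_chains < 2:
        raise StructureError("order parameter needs at least 2 chains")
    first, last = top.chain_order[0], top.chain_order[-1]
    idx_first = top.calpha_indices(first)
    idx_last = top.calpha_indices(last)

    if convention == "reference-fit":
        coords = superpose_trajectory(traj)
        if axis is None or (isinstance(axis, str) and axis == "z"):
            z = np.array([0.0, 0.0, 1.0])
        elif isinstance(axis, str) and axis == "stacking":
            z = _stacking_axis(traj.coordinates[traj.reference_frame], traj)
        else:
            z = np.asarray(axis, dtype=float)
            z = z / np.linalg.norm(z)
        z_per_frame = [z] * traj.n_frames
    elif convention == "per-frame":
        coords = traj.coordinates
        z_per_frame = [_stacking_axis(coords[f], traj) for f in range(traj.n_frames)]
    else:
        raise ValueError(f"unknown convention {convention!r}")

    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        v = coords[f, idx_last] - coords[f, idx_first]
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            r = traj.topology.residue_numbers[int(np.flatnonzero(norms == 0)[0])]
            raise StructureError(f"zero-length cross-fibril vector at residue {r}")
        values[f] = float(np.mean((v @ z_per_frame[f]) / norms))
    return OrdPSeries(values=np.clip(values, -1.0, 1.0), convention=convention, endpoints=(first, last))


def ordp_distribution(series: OrdPSeries, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ordP values: (bin centres, density) over [−1, 1].

    The density integrates to 1 over the support.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if series.n_frames < 1:
        raise ValueError("empty series")
    density, edges = np.histogram(series.values, bins=n_bins, range=(-1.0, 1.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


# ----------------------------------------------------------------------
# Radius of gyration
# ----------------------------------------------------------------------

def radius_of_gyration(
    frame: AssemblyFrame,
    selection: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration (nm) of the selected atoms.

    Masses default to standard atomic masses by element; pass an
    explicit array (e.g. all ones) to override.
    """
    top = frame.topology
    sel = np.arange(top.n_atoms) if selection is None else np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if len(sel) == 0:
        raise ValueError("empty selection")
    xyz = frame.coordinates[sel]
    if masses is None:
        try:
            m = np.array([ATOMIC_MASSES[e] for e in top.element[sel]])
        except KeyError as exc:
            raise ValueError(f"no standard mass for element {exc}") from exc
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (len(sel),):
            raise ValueError("masses must match the selection length")
    com = np.average(xyz, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((xyz - com) ** 2, axis=1), weights=m)))
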