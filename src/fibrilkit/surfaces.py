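"""Solvent-accessible surface area (SASA) and inter-chain buried surface.

SASA is computed with the Shrake–Rupley algorithm: each atom's sphere of
radius (r_vdw + probe) carries a deterministic quasi-uniform point set
(golden-spiral construction, no RNG); a point is accessible when it lies
outside every neighbour's (r_vdw + probe) sphere, and the atom's area is
the accessible fraction of its expanded-sphere area.

The inter-chain interaction surface of residue r in chain X with respect
to a neighbouring chain Y is the SASA it loses when Y is present:
SASA(r | X alone) − SASA(r | X ∪ Y), computed with the same point set.
Each atom's buried contribution is assigned to the hydrophobic (C, S) or
hydrophilic (N, O, H) channel, so the two channels sum to the total by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .core import AssemblyFrame, StructureError, Trajectory
from .core import HYDROPHOBIC, HYDROPHILIC
from .interactions import default_interior_pairs

__all__ = [
    "SasaParams",
    "SasaSeries",
    "InteractionSurfaceProfile",
    "sphere_points",
    "shrake_rupley_sasa",
    "total_sasa",
    "interchain_interaction_surface",
    "BONDI_RADII",
    "UNITED_ATOM_RADII",
]

#: Bondi van der Waals radii, nm.
BONDI_RADII = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "H": 0.120}

#: United-atom radii (hydrogens ignored, heavy radii inflated), nm.
UNITED_ATOM_RADII = {"C": 0.187, "N": 0.170, "O": 0.160, "S": 0.190}


@dataclass(frozen=True)
class SasaParams:
    """Shrake–Rupley parameters.

    probe_radius in nm (default 0.14, a water molecule); n_sphere_points
    controls quadrature accuracy (default 960 points per atom).
    ``united_atom=True`` drops hydrogens and uses inflated heavy radii.
    """

    probe_radius: float = 0.14
    n_sphere_points: int = 960
    radius_table: tuple = tuple(sorted(BONDI_RADII.items()))
    united_atom: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be at least 60")

    @property
    def radii(self) -> dict[str, float]:
        if self.united_atom:
            return dict(UNITED_ATOM_RADII)
        return dict(self.radius_table)

    def with_points(self, n: int) -> "SasaParams":
        return replace(self, n_sphere_points=n)


@dataclass
class SasaSeries:
    """Per-frame total SASA (nm²) with ensemble mean ± std."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())


@dataclass
class InteractionSurfaceProfile:
    """Per-residue inter-chain buried area (nm²), split by hydropathy."""

    residue_numbers: np.ndarray
    total: np.ndarray
    hydrophobic: np.ndarray
    hydrophilic: np.ndarray
    chain_pairs: tuple = ()

    def __post_init__(self) -> None:
        if not np.allclose(self.total, self.hydrophobic + self.hydrophilic, atol=1e-9):
            raise ValueError("hydropathy channels must sum to the total buried area")
        if np.any(self.total < -1e-3):
            raise StructureError("negative buried area beyond quadrature tolerance")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(elements: np.ndarray, params: SasaParams) -> np.ndarray:
    table = params.radii
    try:
        return np.array([table[e] for e in elements])
    except KeyError as exc:
        raise StructureError(f"no van der Waals radius for element {exc}") from exc


def sasa_per_atom(
    coords: np.ndarray, elements: np.ndarray, params: SasaParams
) -> np.ndarray:
    """Shrake–Rupley per-atom SASA (nm²) for an isolated atom set."""
    if params.united_atom:
        keep = elements != "H"
        out = np.zeros(len(elements))
        out[keep] = sasa_per_atom(
            coords[keep], elements[keep], replace(params, united_atom=False,
                                                  radius_table=tuple(sorted(UNITED_ATOM_RADII.items())))
        )
        return out
    radii = _radii_for(elements, params) + params.probe_radius
    n = len(coords)
    unit = sphere_points(params.n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    neighbor_lists = tree.query_ball_point(coords, radii + max_r)
    areas = np.empty(n)
    for i in range(n):
        neigh = np.array([j for j in neighbor_lists[i] if j != i], dtype=int)
        full = 4.0 * np.pi * radii[i] ** 2
        if len(neigh) == 0:
            areas[i] = full
            continue
        pts = coords[i] + radii[i] * unit
        diff = pts[:, None, :] - coords[neigh][None, :, :]
        d2 = np.einsum("pjk,pjk->pj", diff, diff)
        occluded = (d2 <= radii[neigh] ** 2).any(axis=1)
        areas[i] = full * (1.0 - occluded.mean())
    return areas


def shrake_rupley_sasa(
    frame: AssemblyFrame,
    params: SasaParams = SasaParams(),
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA (nm²) of the selected atom set, treated in isolation.

    Atoms outside the selection are ignored entirely (they neither
    receive area nor occlude), which is what makes the pairwise buried-
    area definition well-posed.  Returns one area per selected atom, in
    selection order.
    """
    top = frame.topology
    sel = np.arange(top.n_atoms) if selection is None else np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if len(sel) == 0:
        raise ValueError("empty selection")
    return sasa_per_atom(frame.coordinates[sel], top.element[sel], params)


def total_sasa(traj: Trajectory, params: SasaParams = SasaParams()) -> SasaSeries:
    """Total SASA per frame (nm²), with ensemble mean ± std."""
    values = np.array(
        [shrake_rupley_sasa(traj.frame(f), params).sum() for f in range(traj.n_frames)]
    )
    return SasaSeries(values=values)


def interchain_interaction_surface(
    traj: Trajectory,
    params: SasaParams = SasaParams(),
    chain_pairs=None,
) -> InteractionSurfaceProfile:
    """Per-residue inter-chain buried surface, split by hydropathy.

    For each designated adjacent chain pair (X, Y) and frame, the buried
    area of residue r of X w.r.t. Y is its SASA computed for X alone
    minus its SASA in the X∪Y complex (same point set).  The profile
    averages the two orientations, the designated pairs (default:
    interior pairs) and all frames.
    """
    top = traj.topology
    if chain_pairs is None:
        chain_pairs = default_interior_pairs(top)
    chain_pairs = tuple(tuple(p) for p in chain_pairs)
    res = top.residue_numbers
    n_res = len(res)
    hydropathy = top.hydropathy

    total = np.zeros(n_res)
    phob = np.zeros(n_res)
    phil = np.zeros(n_res)
    n_obs = 0
    for f in range(traj.n_frames):
        coords = traj.coordinates[f]
        alone: dict[str, np.ndarray] = {}
        chains_needed = {c for pair in chain_pairs for c in pair}
        for c in chains_needed:
            sel = np.flatnonzero(top.chain_mask(c))
            alone[c] = sasa_per_atom(coords[sel], top.element[sel], params)
        for x, y in chain_pairs:
            sel_x = np.flatnonzero(top.chain_mask(x))
            sel_y = np.flatnonzero(top.chain_mask(y))
            sel_xy = np.concatenate([sel_x, sel_y])
            complex_areas = sasa_per_atom(coords[sel_xy], top.element[sel_xy], params)
            buried = np.concatenate([alone[x], alone[y]]) - complex_areas
            if np.any(buried < -1e-3):
                raise StructureError(
                    "negative per-atom buried area beyond quadrature tolerance"
                )
            for orient_sel, orient_buried in (
                (sel_x, buried[: len(sel_x)]),
                (sel_y, buried[len(sel_x) :]),
            ):
                res_ids = top.residue_number[orient_sel]
                hp = hydropathy[orient_sel]
                for ri, r in enumerate(res):
                    m = res_ids == r
                    b_phob = orient_buried[m & (hp == HYDROPHOBIC)].sum()
                    b_phil = orient_buried[m & (hp == HYDROPHILIC)].sum()
                    phob[ri] += b_phob
                    phil[ri] += b_phil
                n_obs += 1
    phob /= n_obs
    phil /= n_obs
    total = phob + phil
    return InteractionSurfaceProfile(
        residue_numbers=res,
        total=total,
        hydrophobic=phob,
        hydrophilic=phil,
        chain_pairs=chain_pairs,
    )
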