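"""Core domain types and multi-model PDB I/O for fibril assemblies.

A fibril assembly is an ordered stack of identical peptide chains.  All
coordinates are stored in nanometres; the PDB boundary converts to/from
Ångström.  Chain order along the fibril axis is the order of first
appearance in the source file (A..E for the pentamers this package
targets), and residue numbering is the author numbering of the source
entry (17..42 for the Aβ17–42 systems), never re-indexed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "FibrilTopology",
    "AssemblyFrame",
    "Trajectory",
    "TopologyError",
    "StructureError",
    "TopologyReport",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "validate_topology",
]

ANGSTROM_PER_NM = 10.0

#: Backbone atom roles expected of an H-bond-competent backbone.
BACKBONE_ROLES = ("N", "H", "CA", "C", "O")

HYDROPHOBIC = "hydrophobic"
HYDROPHILIC = "hydrophilic"

#: Atom-level hydropathy partition: carbon and sulfur are apolar, nitrogen,
#: oxygen and their attached hydrogens are polar.
_ELEMENT_HYDROPATHY = {
    "C": HYDROPHOBIC,
    "S": HYDROPHOBIC,
    "N": HYDROPHILIC,
    "O": HYDROPHILIC,
    "H": HYDROPHILIC,
}


class TopologyError(ValueError):
    """Raised when chains/residues do not form a valid fibril topology."""


class StructureError(ValueError):
    """Raised when coordinate data are inconsistent with the topology."""


def element_from_atom_name(atom_name: str) -> str:
    """Infer the element from a PDB atom name.

    The first alphabetic character is the element after standard PDB
    disambiguation (``1HB`` → H, ``CA`` → C, ``OXT`` → O).
    """
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a fibril assembly.

    ``position`` is in nanometres.
    """

    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position must be finite")
        object.__setattr__(self, "position", pos)
        if self.element.upper() != element_from_atom_name(self.atom_name):
            raise ValueError(
                f"element {self.element!r} inconsistent with atom name "
                f"{self.atom_name!r}"
            )


@dataclass
class FibrilTopology:
    """Identity of every atom plus the chain stacking order.

    Array annotations are aligned (one entry per atom).  ``chain_order``
    lists chain ids from the first to the last chain along the fibril
    axis; the order-parameter endpoints are its first and last entries.
    """

    atom_name: np.ndarray
    element: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    chain_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype="U4")
        self.chain_id = np.asarray(self.chain_id, dtype="U2")
        self.chain_order = tuple(self.chain_order)
        n = len(self.atom_name)
        for arr in (self.element, self.residue_number, self.residue_name, self.chain_id):
            if len(arr) != n:
                raise TopologyError("annotation arrays must have equal length")
        missing = set(self.chain_order) - set(self.chain_id.tolist())
        if missing:
            raise TopologyError(f"chain_order lists absent chains: {sorted(missing)}")

    # ------------------------------------------------------------------
    # Derived lookups
    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_chains(self) -> int:
        return len(self.chain_order)

    @property
    def residue_range(self) -> tuple[int, int]:
        """Inclusive (first, last) residue numbers."""
        return int(self.residue_number.min()), int(self.residue_number.max())

    @property
    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue numbers (shared by every chain)."""
        return np.unique(self.residue_number)

    @property
    def n_residues_per_chain(self) -> int:
        first, last = self.residue_range
        return last - first + 1

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def residue_mask(self, chain: str, residue_number: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.residue_number == residue_number)

    def calpha_index(self, chain: str, residue_number: int) -> int:
        """Index of the Cα atom of one residue."""
        idx = np.flatnonzero(self.residue_mask(chain, residue_number) & (self.atom_name == "CA"))
        if len(idx) != 1:
            raise TopologyError(
                f"expected exactly one CA for chain {chain} residue "
                f"{residue_number}, found {len(idx)}"
            )
        return int(idx[0])

    def calpha_indices(self, chain: str | None = None) -> np.ndarray:
        """Cα atom indices in residue order, chain-major in stacking order.

        With ``chain`` given, only that chain's Cαs (residue-ascending).
        """
        if chain is not None:
            mask = (self.atom_name == "CA") & (self.chain_id == chain)
            idx = np.flatnonzero(mask)
            return idx[np.argsort(self.residue_number[idx], kind="stable")]
        return np.concatenate([self.calpha_indices(c) for c in self.chain_order])

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    @property
    def hydropathy(self) -> np.ndarray:
        """Per-atom hydropathy class (C/S apolar, N/O/H polar)."""
        out = np.empty(self.n_atoms, dtype="U12")
        for elem, cls in _ELEMENT_HYDROPATHY.items():
            out[self.element == elem] = cls
        unknown = out == ""
        if np.any(unknown):
            elems = sorted(set(self.element[unknown].tolist()))
            raise TopologyError(f"no hydropathy class for elements {elems}")
        return out

    @property
    def has_hydrogens(self) -> bool:
        return bool(np.any(self.element == "H"))

    def atom_names_of(self, chain: str, residue_number: int) -> tuple[str, ...]:
        return tuple(self.atom_name[self.residue_mask(chain, residue_number)])

    def iter_atoms(self, positions: np.ndarray) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                atom_name=str(self.atom_name[i]),
                element=str(self.element[i]),
                residue_number=int(self.residue_number[i]),
                residue_name=str(self.residue_name[i]),
                chain_id=str(self.chain_id[i]),
                position=positions[i],
            )

    def subset(self, mask: np.ndarray) -> "FibrilTopology":
        """Topology restricted to the atoms selected by a boolean mask."""
        kept_chains = tuple(c for c in self.chain_order if np.any(self.chain_id[mask] == c))
        return FibrilTopology(
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            residue_number=self.residue_number[mask],
            residue_name=self.residue_name[mask],
            chain_id=self.chain_id[mask],
            chain_order=kept_chains,
        )


@dataclass
class AssemblyFrame:
    """One time point of the fibril: topology + coordinates (nm)."""

    topology: FibrilTopology
    coordinates: np.ndarray
    frame_index: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise StructureError(
                f"coordinate array of shape {self.coordinates.shape} does not "
                f"match topology with {self.topology.n_atoms} atoms"
            )


@dataclass
class Trajectory:
    """Ordered frame ensemble sharing one topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3), in nm.  The
    reference frame anchors superposition and the fibril-axis convention.
    """

    topology: FibrilTopology
    coordinates: np.ndarray
    reference_frame: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise StructureError(
                "coordinates must have shape (n_frames, n_atoms, 3) matching "
                "the topology"
            )
        if self.n_frames < 1:
            raise StructureError("trajectory needs at least one frame")
        if not 0 <= self.reference_frame < self.n_frames:
            raise StructureError(
                f"reference_frame {self.reference_frame} outside 0..{self.n_frames - 1}"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> AssemblyFrame:
        return AssemblyFrame(self.topology, self.coordinates[i], frame_index=i, label=self.label)

    def __iter__(self) -> Iterator[AssemblyFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames

    @property
    def reference(self) -> AssemblyFrame:
        return self.frame(self.reference_frame)

    def select_atoms(self, mask: np.ndarray) -> "Trajectory":
        return Trajectory(
            topology=self.topology.subset(mask),
            coordinates=self.coordinates[:, mask, :],
            reference_frame=self.reference_frame,
            label=self.label,
        )

    def select_residue_window(self, first_residue: int, last_residue: int) -> "Trajectory":
        """Keep residues in the inclusive window; idempotent."""
        mask = (self.topology.residue_number >= first_residue) & (
            self.topology.residue_number <= last_residue
        )
        if not np.any(mask):
            raise TopologyError(
                f"no atoms in residue window [{first_residue}, {last_residue}]"
            )
        return self.select_atoms(mask)


# ----------------------------------------------------------------------
# Multi-model PDB I/O (biotite behind the interface; Å ↔ nm here)
# ----------------------------------------------------------------------

def _check_window(
    chain_ids: np.ndarray, res_ids: np.ndarray, first_residue: int, last_residue: int
) -> None:
    for chain in np.unique(chain_ids):
        present = set(res_ids[chain_ids == chain].tolist())
        for r in range(first_residue, last_residue + 1):
            if r not in present:
                raise TopologyError(f"chain {chain} is missing residue {r}")


def read_multimodel_pdb(
    path: str | Path, first_residue: int, last_residue: int
) -> Trajectory:
    """Read a multi-model PDB into a Trajectory, windowed to a residue range.

    Every MODEL block becomes one frame.  Coordinates are converted from
    Å to nm.  Chain order is order of first appearance.  The requested
    residue window must be present in every chain; residues outside it
    are discarded.  Only the first alternate location is kept; insertion
    codes are rejected.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb_file = PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on ragged models
        raise StructureError(f"inconsistent atom sets across models: {exc}") from exc
    if stack.stack_depth() < 1:
        raise StructureError("file contains no models")
    ins = stack.get_annotation("ins_code") if "ins_code" in stack.get_annotation_categories() else None
    if ins is not None and np.any(np.char.strip(ins.astype("U4")) != ""):
        raise StructureError("insertion codes are not supported for fibril models")

    chain_ids = stack.chain_id.astype("U2")
    res_ids = stack.res_id.astype(int)
    _check_window(chain_ids, res_ids, first_residue, last_residue)

    keep = (res_ids >= first_residue) & (res_ids <= last_residue)
    chain_ids = chain_ids[keep]
    res_ids = res_ids[keep]
    atom_names = stack.atom_name.astype("U6")[keep]
    res_names = stack.res_name.astype("U4")[keep]
    elements = stack.element.astype("U2")[keep]
    blank = elements == ""
    if np.any(blank):
        elements = elements.copy()
        elements[blank] = [element_from_atom_name(a) for a in atom_names[blank]]

    seen: list[str] = []
    for c in chain_ids:
        if c not in seen:
            seen.append(str(c))

    topology = FibrilTopology(
        atom_name=atom_names,
        element=elements,
        residue_number=res_ids,
        residue_name=res_names,
        chain_id=chain_ids,
        chain_order=tuple(seen),
    )
    coords_nm = np.asarray(stack.coord, dtype=float)[:, keep, :] / ANGSTROM_PER_NM
    return Trajectory(topology=topology, coordinates=coords_nm)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a standards-compliant multi-model PDB (Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = traj.topology
    atoms = struc.AtomArray(top.n_atoms)
    atoms.chain_id = top.chain_id.astype("U4")
    atoms.res_id = top.residue_number.astype(int)
    atoms.res_name = top.residue_name.astype("U5")
    atoms.atom_name = top.atom_name.astype("U6")
    atoms.element = top.element.astype("U2")
    atoms.hetero = np.zeros(top.n_atoms, dtype=bool)
    stack = struc.stack([atoms] * traj.n_frames)
    stack.coord = traj.coordinates * ANGSTROM_PER_NM
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    if traj.n_frames == 1:
        # keep the MODEL/ENDMDL wrapper even for a single model
        text = Path(path).read_text()
        if "MODEL" not in text:
            Path(path).write_text("MODEL        1\n" + text + "ENDMDL\n")


# ----------------------------------------------------------------------
# Topology validation report
# ----------------------------------------------------------------------

@dataclass
class TopologyReport:
    """Report-only summary of a trajectory's topology."""

    n_chains: int
    chain_order: tuple[str, ...]
    n_residues_per_chain: int
    residue_range: tuple[int, int]
    atom_roles: tuple[str, ...]
    has_hydrogens: bool
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        lines = [
            f"chains: {self.n_chains} ({', '.join(self.chain_order)})",
            f"residues per chain: {self.n_residues_per_chain} "
            f"[{self.residue_range[0]}-{self.residue_range[1]}]",
            f"atom roles: {', '.join(self.atom_roles)}",
            f"explicit hydrogens: {'yes' if self.has_hydrogens else 'no (no explicit hydrogens)'}",
        ]
        for issue in self.issues:
            lines.append(f"ISSUE: {issue}")
        return "\n".join(lines)


def validate_topology(traj: Trajectory) -> TopologyReport:
    """Check chain/residue/atom-role consistency of a trajectory.

    Report-only: never raises.  Flags missing backbone roles per residue,
    ragged chains and absent hydrogens (which affects the hydrogen-bond
    criterion choice downstream).
    """
    top = traj.topology
    issues: list[str] = []
    first, last = top.residue_range

    roles_seen = sorted(set(top.atom_name.tolist()), key=lambda a: (len(a), a))
    reference_atoms: dict[int, tuple[str, ...]] | None = None
    for chain in top.chain_order:
        chain_res = top.residue_number[top.chain_mask(chain)]
        chain_atoms: dict[int, tuple[str, ...]] = {}
        for r in range(first, last + 1):
            if r not in chain_res:
                issues.append(f"chain {chain} missing residue {r}")
                continue
            chain_atoms[r] = top.atom_names_of(chain, r)
            for role in ("N", "CA", "C", "O"):
                if role not in chain_atoms[r]:
                    issues.append(f"chain {chain} residue {r} missing atom {role}")
        if reference_atoms is None:
            reference_atoms = chain_atoms
        else:
            for r, names in chain_atoms.items():
                ref = reference_atoms.get(r)
                if ref is not None and sorted(names) != sorted(ref):
                    issues.append(
                        f"chain {chain} residue {r} atom set differs from chain "
                        f"{top.chain_order[0]}"
                    )
    if not top.has_hydrogens:
        issues.append("no explicit hydrogens (H-bond detection will be distance-only)")

    return TopologyReport(
        n_chains=top.n_chains,
        chain_order=top.chain_order,
        n_residues_per_chain=top.n_residues_per_chain,
        residue_range=top.residue_range,
        atom_roles=tuple(roles_seen),
        has_hydrogens=top.has_hydrogens,
        issues=issues,
    )
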