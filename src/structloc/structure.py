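"""Atomic structures: domain types, PDB I/O, selections.

Coordinates are Å in a right-handed frame. Residue numbering is taken
verbatim from the input file. Alternate locations are resolved on read to
the highest-occupancy conformer (ties broken by alt-loc letter order).
Hydrogens are parsed but excluded from all downstream geometry by default;
HETATM records likewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import gemmi

from .errors import EmptySelectionError, FormatError

# Bundled per-element VDW radii (Å). Elements not listed fall back to 1.70.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.80, "ZN": 1.39, "CA": 1.70, "MG": 1.73, "K": 2.75,
    "NA": 2.27, "MN": 1.73, "SE": 1.90,
}
DEFAULT_VDW = 1.70

# Atomic numbers for map simulation weights.
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "ZN": 30,
    "SE": 34, "BR": 35, "I": 53,
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def atomic_number(element: str) -> int:
    return ATOMIC_NUMBERS.get(element.upper(), 6)


@dataclass
class Atom:
    serial: int
    element: str
    vdw_radius: float
    coord: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0
    chain_id: str = "A"
    residue_number: int = 1
    residue_name: str = "ALA"
    atom_name: str = "CA"
    is_hetatm: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinate must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class SSESegment:
    """A secondary-structure element: contiguous residue range in one chain."""

    kind: str  # helix | strand | loop
    chain_id: str
    start_residue: int
    end_residue: int
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("helix", "strand", "loop"):
            raise ValueError(f"unknown SSE kind {self.kind!r}")
        if self.start_residue > self.end_residue:
            raise ValueError("start_residue must be <= end_residue")


@dataclass
class AtomicStructure:
    """A collection of atoms with optional secondary-structure annotation."""

    atoms: list[Atom] = field(default_factory=list)
    sse_annotation: list[SSESegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for a in self.atoms], dtype=float)

    def heavy_atoms(self, include_hetatm: bool = False) -> list[Atom]:
        """Non-hydrogen atoms used by all downstream geometry."""
        return [
            a for a in self.atoms
            if a.element.upper() != "H" and (include_hetatm or not a.is_hetatm)
        ]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for a in atoms], dtype=float)

    def centroid(self) -> np.ndarray:
        """Centroid of heavy atoms (all atoms if no heavies)."""
        c = self.heavy_coords()
        if len(c) == 0:
            c = self.coords()
        if len(c) == 0:
            raise EmptySelectionError("cannot take centroid of empty structure")
        return c.mean(axis=0)

    def select_chain(self, chain_id: str) -> "AtomicStructure":
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        if not atoms:
            raise EmptySelectionError(f"no atoms in chain {chain_id!r}")
        sse = [s for s in self.sse_annotation if s.chain_id == chain_id]
        return AtomicStructure(atoms=atoms, sse_annotation=sse)

    def select_residues(self, chain_id: str, start: int, end: int) -> "AtomicStructure":
        atoms = [
            a for a in self.atoms
            if a.chain_id == chain_id and start <= a.residue_number <= end
        ]
        return AtomicStructure(atoms=atoms)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray | None = None) -> "AtomicStructure":
        """Rigidly transform: x -> R (x - c) + c + t (c defaults to origin)."""
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = [
            replace(a, coord=R @ (a.coord - c) + c + t) for a in self.atoms
        ]
        return AtomicStructure(atoms=new_atoms, sse_annotation=list(self.sse_annotation))

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs of heavy atoms."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.heavy_atoms():
            seen.setdefault((a.chain_id, a.residue_number), None)
        return list(seen)


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties by alt-loc letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in residue:
        by_name.setdefault(at.name, []).append(at)
    out = []
    for name, group in by_name.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(max(group, key=lambda a: (a.occ, -ord(a.altloc or "A"))))
    return out


def read_structure(path, chain_filter: str | None = None) -> AtomicStructure:
    """Read a PDB file into an AtomicStructure.

    Only the requested chain is returned when ``chain_filter`` is given.
    Alt-locs are resolved to the highest-occupancy conformer; VDW radii are
    assigned from the bundled element table. HETATM records are parsed and
    flagged (downstream geometry skips them by default).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read structure from {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models found in {path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for residue in chain:
            is_het = residue.het_flag == "H"
            for at in _resolve_altlocs(residue):
                elem = at.element.name if at.element else "C"
                atoms.append(Atom(
                    serial=at.serial,
                    element=elem,
                    vdw_radius=vdw_radius(elem),
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_factor=at.b_iso,
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    residue_name=residue.name,
                    atom_name=at.name,
                    is_hetatm=is_het,
                ))
    if not atoms:
        if chain_filter is not None:
            raise EmptySelectionError(f"chain {chain_filter!r} not found in {path}")
        raise FormatError(f"no atoms parsed from {path}")
    return AtomicStructure(atoms=atoms)


def _pdb_atom_name(name: str, element: str) -> str:
    # Single-letter elements start in column 14 (index 13) per PDB convention.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: AtomicStructure, path) -> str:
    """Write fixed-column PDB ATOM/HETATM records, coordinates to 3 decimals."""
    if not structure.atoms:
        raise EmptySelectionError("refusing to write an empty structure")
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.is_hetatm else "ATOM  "
        lines.append(
            f"{record}{a.serial % 100000:5d} {_pdb_atom_name(a.atom_name, a.element)}"
            f" {a.residue_name:<3s} {a.chain_id[:1]}{a.residue_number:4d}    "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element.upper():>2s}  "
        )
    lines.append("END")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise FormatError(f"cannot write structure to {path}: {exc}") from exc
    return str(path)
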