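"""Quantitative model comparison: superposition, per-residue RMSD profiles,
per-segment map correlation, solvent accessibility, interfaces and contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .density import DensityMap, cross_correlation, simulate_on_grid
from .errors import DegenerateGeometryError, EmptySelectionError
from .structure import Atom, AtomicStructure, SSESegment

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class RmsdProfile:
    """Per-residue RMSD after one global superposition."""

    residue_numbers: list[int]
    rmsd: np.ndarray
    alignment_note: str = ""


@dataclass
class InterfaceReport:
    buried_area: float                      # Å², half the total SASA loss
    buried_area_total: float                # Å², total SASA loss
    contact_pairs: list[tuple] = field(default_factory=list)
    # each pair: (chain/resnum/resname of A, same of B, min atom distance Å)


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition of b onto a.

    Returns (rotation, translation, rmsd) such that applying
    ``R @ b.T + t`` minimizes the RMSD to a. The rotation is always proper
    (determinant +1); reflections are corrected by sign flip.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    if len(a) < 3:
        raise DegenerateGeometryError("need >= 3 points for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb).T @ (a - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = b @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return R, t, rmsd


def _selected_atoms(structure: AtomicStructure, atoms: str) -> dict:
    """Map (chain, resnum, atom_name) -> coord for the atom selection."""
    out = {}
    for a in structure.heavy_atoms():
        if atoms == "CA-only" and a.atom_name != "CA":
            continue
        if atoms == "backbone" and a.atom_name not in BACKBONE_NAMES:
            continue
        out[(a.chain_id, a.residue_number, a.atom_name)] = a.coord
    return out


def per_residue_rmsd(model_a: AtomicStructure, model_b: AtomicStructure,
                     pairing: dict[int, int] | None = None,
                     atoms: str = "CA-only") -> RmsdProfile:
    """Per-residue RMSD profile after one global superposition.

    ``pairing`` maps residue numbers of model_a to model_b (identity when
    None). One Kabsch superposition over all paired selected atoms, then the
    RMSD of each residue's selected atoms. Residues missing atoms in either
    model are skipped and listed in the alignment note.
    """
    if atoms not in ("CA-only", "backbone", "all-heavy"):
        raise ValueError(f"unknown atom selection {atoms!r}")
    sel_a = _selected_atoms(model_a, atoms)
    sel_b = _selected_atoms(model_b, atoms)
    res_a = sorted({(c, r) for c, r, _ in sel_a})
    if pairing is None:
        pairing = {r: r for _, r in res_a}
    if not pairing:
        raise EmptySelectionError("empty residue pairing")

    paired: dict[tuple[str, int], list[tuple[np.ndarray, np.ndarray]]] = {}
    skipped = []
    for chain, rnum in res_a:
        if rnum not in pairing:
            continue
        rnum_b = pairing[rnum]
        names_a = [n for c, r, n in sel_a if c == chain and r == rnum]
        pairs = []
        complete = True
        for n in names_a:
            key_b = (chain, rnum_b, n)
            if key_b not in sel_b:
                complete = False
                break
            pairs.append((sel_a[(chain, rnum, n)], sel_b[key_b]))
        if complete and pairs:
            paired[(chain, rnum)] = pairs
        else:
            skipped.append(f"{chain}{rnum}")
    if not paired:
        raise EmptySelectionError("no residues could be paired with the requested atoms")

    all_a = np.array([p[0] for plist in paired.values() for p in plist])
    all_b = np.array([p[1] for plist in paired.values() for p in plist])
    R, t, _ = kabsch_superpose(all_a, all_b)

    residue_numbers, rmsds = [], []
    for (chain, rnum), plist in paired.items():
        pa = np.array([p[0] for p in plist])
        pb = np.array([p[1] for p in plist]) @ R.T + t
        rmsds.append(np.sqrt(np.mean(np.sum((pb - pa) ** 2, axis=1))))
        residue_numbers.append(rnum)
    note = f"atoms={atoms}; paired {len(residue_numbers)} residues"
    if skipped:
        note += "; skipped (missing atoms): " + ",".join(skipped)
    return RmsdProfile(residue_numbers=residue_numbers,
                       rmsd=np.array(rmsds), alignment_note=note)


def per_sse_map_cc(model: AtomicStructure, density_map: DensityMap,
                   resolution: float, local_radius: float = 3.0):
    """Cross-correlation between map and model density per secondary-structure
    element, over voxels within ``local_radius`` of the segment's atoms."""
    if not model.sse_annotation:
        raise EmptySelectionError("model carries no SSE annotation")
    simulated = simulate_on_grid(model, resolution, density_map)
    ax = [density_map.voxel_centers_axis(d) for d in range(3)]
    gi, gj, gk = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    voxel_xyz = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1)
    tree = cKDTree(voxel_xyz)
    results = []
    for seg in model.sse_annotation:
        seg_atoms = model.select_residues(seg.chain_id, seg.start_residue,
                                          seg.end_residue).heavy_coords()
        if len(seg_atoms) == 0:
            warnings.warn(f"SSE segment {seg.label or seg.kind} has no atoms; skipped",
                          stacklevel=2)
            continue
        idx = sorted(set(i for lst in tree.query_ball_point(seg_atoms, local_radius)
                         for i in lst))
        if not idx:
            warnings.warn(f"SSE segment {seg.label or seg.kind} covers no voxels; "
                          "skipped", stacklevel=2)
            continue
        a = density_map.values.ravel()[idx]
        b = simulated.values.ravel()[idx]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        cc = float((a @ b) / denom) if denom > 0 else 0.0
        results.append((seg, cc))
    return results


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform deterministic points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(structure: AtomicStructure, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per heavy atom (Å²).

    Each atom's expanded sphere (vdw + probe) is sampled with a deterministic
    near-uniform quadrature; the unoccluded fraction times the sphere area is
    that atom's SASA.
    """
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be >= 92")
    atoms = structure.heavy_atoms()
    if not atoms:
        raise EmptySelectionError("no heavy atoms for SASA")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    unit = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(atoms))
    max_r = radii.max()
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                 if j != i]
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :], axis=2)
            buried = (d < radii[neigh][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def interface_report(chain_a: AtomicStructure, chain_b: AtomicStructure,
                     probe_radius: float = 1.4,
                     contact_cutoff: float = 0.4) -> InterfaceReport:
    """Buried surface area and VDW contact pairs between two chains.

    buried_area = (SASA(A) + SASA(B) - SASA(A u B)) / 2 (per complex; the
    total loss is also reported). Contacts are residue pairs with any
    inter-atomic distance <= vdw_a + vdw_b + contact_cutoff.
    """
    if not chain_a.atoms or not chain_b.atoms:
        raise EmptySelectionError("both chains must be non-empty")
    sasa_a = sasa(chain_a, probe_radius).sum()
    sasa_b = sasa(chain_b, probe_radius).sum()
    combined = AtomicStructure(atoms=list(chain_a.atoms) + list(chain_b.atoms))
    sasa_ab = sasa(combined, probe_radius).sum()
    total_loss = max(sasa_a + sasa_b - sasa_ab, 0.0)

    atoms_a = chain_a.heavy_atoms()
    atoms_b = chain_b.heavy_atoms()
    ca = np.array([a.coord for a in atoms_a])
    cb = np.array([a.coord for a in atoms_b])
    max_cut = (max(a.vdw_radius for a in atoms_a)
               + max(b.vdw_radius for b in atoms_b) + contact_cutoff)
    tree_b = cKDTree(cb)
    contacts: dict[tuple, float] = {}
    for i, a in enumerate(atoms_a):
        for j in tree_b.query_ball_point(ca[i], max_cut):
            b = atoms_b[j]
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if d <= a.vdw_radius + b.vdw_radius + contact_cutoff:
                key = ((a.chain_id, a.residue_number, a.residue_name),
                       (b.chain_id, b.residue_number, b.residue_name))
                contacts[key] = min(contacts.get(key, np.inf), d)
    pairs = [(ka, kb, d) for (ka, kb), d in sorted(contacts.items())]
    return InterfaceReport(buried_area=total_loss / 2.0,
                           buried_area_total=total_loss,
                           contact_pairs=pairs)
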