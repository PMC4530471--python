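"""3D localization of a fluorescent acceptor from FRET distance constraints.

Given >= 3 donor positions with measured donor-acceptor distances, the
acceptor is localized two ways:

* :func:`shell_locus` — the intersection of spherical shells, computed on a
  regular grid and returned as an occupancy volume (exportable as an MRC map
  so any viewer renders the locus as a volume);
* :func:`point_estimate` — weighted nonlinear least squares on the shell
  residuals, with the mirror ambiguity of the 3-donor case detected and both
  solutions reported.

:func:`place_probe` models the dye position attached via a flexible linker:
uniform samples in the linker-length ball around the attachment atom, with
sterically clashing samples rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .density import DensityMap
from .errors import BuriedSiteError, DegenerateGeometryError, UnderDeterminedError
from .fret import DistanceConstraint
from .structure import AtomicStructure


@dataclass
class LocusVolume:
    """Occupancy grid of positions consistent with all distance constraints."""

    grid: np.ndarray            # boolean occupancy, X-fastest indexing
    voxel_size: float
    origin: np.ndarray
    constraints_used: list[DistanceConstraint] = field(default_factory=list)
    tolerances: np.ndarray | None = None  # per-constraint shell tolerance (Å)

    @property
    def volume(self) -> float:
        """Occupied volume in Å³."""
        return float(self.grid.sum()) * self.voxel_size**3

    @property
    def centroid(self) -> np.ndarray | None:
        """Mean position of occupied voxel centers (None when empty)."""
        idx = np.argwhere(self.grid)
        if idx.size == 0:
            return None
        return self.origin + self.voxel_size * idx.mean(axis=0)

    def contains(self, point: np.ndarray) -> bool:
        """True if ``point`` lies in the continuous shell-intersection locus.

        Membership is evaluated against the analytic shell predicate (the
        grid is a rendering of that region at voxel resolution); when the
        constraints are unavailable it falls back to the occupancy of the
        voxel containing the point.
        """
        p = np.asarray(point, float)
        if self.constraints_used and self.tolerances is not None:
            for c, tol in zip(self.constraints_used, self.tolerances):
                if abs(np.linalg.norm(p - c.donor_coord) - c.distance) > tol:
                    return False
            return True
        ijk = np.round((p - self.origin) / self.voxel_size).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.grid.shape):
            return False
        return bool(self.grid[tuple(ijk)])

    def to_density_map(self) -> DensityMap:
        return DensityMap(values=self.grid.astype(float),
                          voxel_size=self.voxel_size, origin=self.origin.copy())


@dataclass
class ProbeModel:
    """Dye attached to a structure atom by a flexible linker."""

    attachment_atom: int        # index into AtomicStructure.atoms
    linker_length: float = 20.0  # Å
    clash_distance: float = 3.0  # Å
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.linker_length <= 0:
            raise ValueError("linker_length must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def shell_locus(constraints: list[DistanceConstraint], grid_step: float = 2.0,
                tolerance_scale: float = 1.0) -> LocusVolume:
    """Intersect spherical shells | ||x - donor_i|| - r_i | <= tol_i.

    tol_i = max(grid_step, tolerance_scale * uncertainty_i). The grid spans
    the union of the shells' bounding boxes. An empty intersection returns a
    locus with volume 0 (not an error).
    """
    if len(constraints) < 3:
        raise UnderDeterminedError("shell locus requires >= 3 distance constraints")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    tols = np.array([max(grid_step, tolerance_scale * c.uncertainty)
                     for c in constraints])
    donors = np.array([c.donor_coord for c in constraints])
    radii = np.array([c.distance for c in constraints])
    lo = (donors - (radii + tols)[:, None]).min(axis=0)
    hi = (donors + (radii + tols)[:, None]).max(axis=0)
    shape = np.floor((hi - lo) / grid_step).astype(int) + 1
    ax = [lo[d] + grid_step * np.arange(shape[d]) for d in range(3)]
    occ = np.ones(tuple(shape), dtype=bool)
    for donor, r, tol in zip(donors, radii, tols):
        dx2 = (ax[0] - donor[0])[:, None, None] ** 2
        dy2 = (ax[1] - donor[1])[None, :, None] ** 2
        dz2 = (ax[2] - donor[2])[None, None, :] ** 2
        dist = np.sqrt(dx2 + dy2 + dz2)
        occ &= np.abs(dist - r) <= tol
        if not occ.any():
            break
    return LocusVolume(grid=occ, voxel_size=grid_step, origin=lo,
                       constraints_used=list(constraints), tolerances=tols)


@dataclass
class PointEstimate:
    coord: np.ndarray
    rms_residual: float
    ambiguity_flag: bool = False
    alternate_coord: np.ndarray | None = None


def _linearized_solution(donors: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Closed-form linearized multilateration (difference of squared shells)."""
    d0, r0 = donors[0], radii[0]
    A = 2.0 * (donors[1:] - d0)
    b = (np.sum(donors[1:] ** 2, axis=1) - np.sum(d0**2)
         - radii[1:] ** 2 + r0**2)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol


def _solve_from(start: np.ndarray, donors: np.ndarray, radii: np.ndarray,
                weights: np.ndarray):
    def resid(x):
        return weights * (np.linalg.norm(x - donors, axis=1) - radii)

    res = least_squares(resid, start, method="lm", xtol=1e-12, ftol=1e-12)
    return res.x, float(np.sqrt(np.mean(resid(res.x) ** 2 / weights**2)))


def point_estimate(constraints: list[DistanceConstraint]) -> PointEstimate:
    """Weighted least-squares acceptor position from distance constraints.

    Minimizes sum_i w_i (||x - donor_i|| - r_i)^2 with w_i = 1/uncertainty_i^2
    (unit weights when any uncertainty is absent/zero). Multi-start from the
    donor centroid, the linearized closed-form solution, and points offset
    from each donor. With exactly 3 non-collinear donors the mirror solution
    across the donor plane is also returned and the ambiguity flag set.
    """
    if len(constraints) < 3:
        raise UnderDeterminedError("point estimate requires >= 3 distance constraints")
    donors = np.array([c.donor_coord for c in constraints])
    radii = np.array([c.distance for c in constraints])
    unc = np.array([c.uncertainty for c in constraints])
    centered = donors - donors.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateGeometryError("donor positions are collinear")
    weights = 1.0 / unc if np.all(unc > 0) else np.ones(len(constraints))

    centroid = donors.mean(axis=0)
    starts = [centroid, _linearized_solution(donors, radii)]
    for d, r in zip(donors, radii):
        direction = centroid - d
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        starts.append(d + r * direction)
    # the objective is mirror-symmetric about the donor best-fit plane, so
    # in-plane starts can never leave it: add starts offset along the normal
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    mean_r = float(radii.mean())
    starts.append(centroid + mean_r * normal)
    starts.append(centroid - mean_r * normal)

    best, best_rms = None, np.inf
    for s in starts:
        x, rms = _solve_from(np.asarray(s, float), donors, radii, weights)
        if rms < best_rms - 1e-12:
            best, best_rms = x, rms

    ambiguity = False
    alternate = None
    if len(constraints) == 3:
        # mirror across the donor plane and re-optimize
        normal = np.cross(donors[1] - donors[0], donors[2] - donors[0])
        normal /= np.linalg.norm(normal)
        mirrored = best - 2.0 * np.dot(best - donors[0], normal) * normal
        alt, alt_rms = _solve_from(mirrored, donors, radii, weights)
        if np.linalg.norm(alt - best) > 1e-6 and alt_rms <= best_rms + 1e-6:
            ambiguity = True
            alternate = alt
    return PointEstimate(coord=best, rms_residual=best_rms,
                         ambiguity_flag=ambiguity, alternate_coord=alternate)


def place_probe(structure: AtomicStructure, probe: ProbeModel):
    """Accessible-volume dye placement around an attachment atom.

    Draws ``n_samples`` uniform points in the ball of radius linker_length
    about the attachment atom; points within clash_distance of any other
    protein heavy atom are rejected. Returns (mean accepted position,
    accepted cloud). Deterministic given the probe seed.
    """
    if not 0 <= probe.attachment_atom < len(structure.atoms):
        raise IndexError("attachment_atom index out of range")
    anchor = structure.atoms[probe.attachment_atom].coord
    rng = np.random.default_rng(probe.seed)
    # uniform in ball: isotropic direction x cube-root radial law
    directions = rng.normal(size=(probe.n_samples, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = probe.linker_length * rng.random(probe.n_samples) ** (1.0 / 3.0)
    samples = anchor + directions * radii[:, None]

    obstacles = [a.coord for i, a in enumerate(structure.atoms)
                 if i != probe.attachment_atom and a.element.upper() != "H"
                 and not a.is_hetatm]
    if obstacles:
        tree = cKDTree(np.array(obstacles))
        d, _ = tree.query(samples, k=1)
        accepted = samples[d >= probe.clash_distance]
    else:
        accepted = samples
    if len(accepted) == 0:
        raise BuriedSiteError("no sterically allowed probe positions "
                              "(attachment site fully buried)")
    return accepted.mean(axis=0), accepted
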